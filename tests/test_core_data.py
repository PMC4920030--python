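"""Loading, Mendelian validation, MAF filtering and result serialization."""

import numpy as np
import pandas as pd
import pytest

from conada.core_data import (
    RegionDataset,
    check_mendelian,
    filter_by_maf,
    founder_frequencies,
    load_dataset,
    write_genotypes_tsv,
    write_pedigree,
    write_results,
    write_vcf,
)
from conada.permutation_engine import SequentialConfig, run_conada

from conftest import make_variants, random_trio_dataset

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
)


def write_trio_vcf(path, rows, samples):
    path.write_text(VCF_HEADER + "\t".join(samples) + "\n" + "".join(rows))


def write_ped(path, trios, controls=()):
    lines = []
    for child, fa, mo in trios:
        lines.append(f"f\t{fa}\t0\t0\t1\t0\n")
        lines.append(f"f\t{mo}\t0\t0\t2\t0\n")
        lines.append(f"f\t{child}\t{fa}\t{mo}\t0\t2\n")
    for c in controls:
        lines.append(f"f\t{c}\t0\t0\t0\t1\n")
    path.write_text("".join(lines))


class TestLoadVcf:
    def test_basic_trio_parse(self, tmp_path):
        samples = ["fa", "mo", "kid"]
        rows = [
            "1\t100\tv1\tA\tC\t.\t.\t.\tGT\t0/1\t0/0\t0/1\n",
            "1\t200\tv2\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t0/1\n",
        ]
        write_trio_vcf(tmp_path / "x.vcf", rows, samples)
        write_ped(tmp_path / "x.ped", [("kid", "fa", "mo")])
        ds = load_dataset(tmp_path / "x.vcf", tmp_path / "x.ped")
        assert ds.n_variants == 2 and ds.n_trios == 1
        assert ds.child[0].tolist() == [1.0, 1.0]

    def test_missing_sample_is_an_error(self, tmp_path):
        write_trio_vcf(
            tmp_path / "x.vcf",
            ["1\t100\tv1\tA\tC\t.\t.\t.\tGT\t0/1\t0/0\n"],
            ["fa", "kid"],
        )
        write_ped(tmp_path / "x.ped", [("kid", "fa", "mo")])
        with pytest.raises(ValueError, match="sample not found.*mo"):
            load_dataset(tmp_path / "x.vcf", tmp_path / "x.ped")

    def test_region_restricts_sites(self, tmp_path):
        samples = ["fa", "mo", "kid"]
        rows = [
            f"1\t{pos}\tv{k}\tA\tC\t.\t.\t.\tGT\t0/1\t0/0\t0/1\n"
            for k, pos in enumerate([100, 200, 300], 1)
        ]
        write_trio_vcf(tmp_path / "x.vcf", rows, samples)
        write_ped(tmp_path / "x.ped", [("kid", "fa", "mo")])
        ds = load_dataset(tmp_path / "x.vcf", tmp_path / "x.ped", region="1:150-250")
        assert ds.n_variants == 1
        assert ds.variants[0].pos == 200

    def test_minor_allele_orientation_flips_major_alt(self, tmp_path):
        # ALT is carried by nearly all founders -> scores must count REF
        samples = ["fa", "mo", "kid", "c1"]
        rows = ["1\t100\tv1\tA\tC\t.\t.\t.\tGT\t1/1\t1/1\t1/1\t0/1\n"]
        write_trio_vcf(tmp_path / "x.vcf", rows, samples)
        write_ped(tmp_path / "x.ped", [("kid", "fa", "mo")], controls=["c1"])
        ds = load_dataset(tmp_path / "x.vcf", tmp_path / "x.ped")
        assert ds.variants[0].minor_allele == "A"
        assert ds.father[0, 0] == 0.0 and ds.controls[0, 0] == 1.0

    def test_multiallelic_rejected_then_split(self, tmp_path):
        samples = ["fa", "mo", "kid"]
        rows = ["1\t100\tv1\tA\tC,G\t.\t.\t.\tGT\t0/1\t0/2\t1/2\n"]
        write_trio_vcf(tmp_path / "x.vcf", rows, samples)
        write_ped(tmp_path / "x.ped", [("kid", "fa", "mo")])
        with pytest.raises(ValueError, match="multi-allelic"):
            load_dataset(tmp_path / "x.vcf", tmp_path / "x.ped")
        ds = load_dataset(
            tmp_path / "x.vcf", tmp_path / "x.ped", split_multiallelic=True
        )
        assert ds.n_variants == 2

    def test_mendelian_policy(self, tmp_path):
        samples = ["fa", "mo", "kid"]
        rows = ["1\t100\tv1\tA\tC\t.\t.\t.\tGT\t0/0\t0/0\t0/1\n"]
        write_trio_vcf(tmp_path / "x.vcf", rows, samples)
        write_ped(tmp_path / "x.ped", [("kid", "fa", "mo")])
        with pytest.raises(ValueError, match="Mendelian"):
            load_dataset(tmp_path / "x.vcf", tmp_path / "x.ped")
        ds = load_dataset(
            tmp_path / "x.vcf", tmp_path / "x.ped", mendelian_policy="set-missing"
        )
        assert np.isnan(ds.child[0, 0])


class TestRoundTrip:
    def test_vcf_roundtrip_is_idempotent(self, tmp_path, rng):
        ds = random_trio_dataset(rng, n=10, L=6, n_controls=5)
        write_vcf(ds, tmp_path / "a.vcf")
        write_pedigree(ds, tmp_path / "a.ped")
        ds2 = load_dataset(tmp_path / "a.vcf", tmp_path / "a.ped")
        np.testing.assert_array_equal(ds.child, ds2.child)
        np.testing.assert_array_equal(ds.father, ds2.father)
        np.testing.assert_array_equal(ds.controls, ds2.controls)
        write_vcf(ds2, tmp_path / "b.vcf")
        assert (tmp_path / "a.vcf").read_text() == (tmp_path / "b.vcf").read_text()

    def test_tsv_roundtrip(self, tmp_path, rng):
        ds = random_trio_dataset(rng, n=6, L=4, n_controls=3)
        write_genotypes_tsv(ds, tmp_path / "a.tsv")
        write_pedigree(ds, tmp_path / "a.ped")
        ds2 = load_dataset(tmp_path / "a.tsv", tmp_path / "a.ped")
        np.testing.assert_array_equal(ds.mother, ds2.mother)
        np.testing.assert_array_equal(ds.child, ds2.child)


class TestMendelianCheck:
    @pytest.mark.parametrize(
        "f,m,c,expect_violation",
        [
            (0, 0, 1, True),
            (1, 1, 0, False),
            (1, 1, 1, False),
            (1, 1, 2, False),
            (2, 0, 1, False),
            (2, 0, 0, True),
            (2, 2, 1, True),
            (0, 2, 1, False),
        ],
    )
    def test_single_cell(self, f, m, c, expect_violation):
        ds = RegionDataset(
            variants=make_variants(1),
            trio_ids=["t"],
            father=np.array([[float(f)]]),
            mother=np.array([[float(m)]]),
            child=np.array([[float(c)]]),
        )
        hits = check_mendelian(ds)
        assert bool(hits) is expect_violation
        if hits:
            assert hits == [("t", "v1")]

    def test_missing_member_never_flagged(self):
        ds = RegionDataset(
            variants=make_variants(1),
            trio_ids=["t"],
            father=np.array([[0.0]]),
            mother=np.array([[0.0]]),
            child=np.array([[np.nan]]),
        )
        assert check_mendelian(ds) == []

    def test_simulated_datasets_are_clean(self, rng):
        for _ in range(20):
            assert check_mendelian(random_trio_dataset(rng)) == []


class TestMafFilter:
    def build(self, freqs, n_founder_pairs=50):
        # founders homozygous in fixed proportions so founder freq is exact
        rng = np.random.default_rng(1)
        L = len(freqs)
        n = n_founder_pairs
        F = np.zeros((n, L))
        M = np.zeros((n, L))
        for l, f in enumerate(freqs):
            k = int(round(2 * f * 2 * n))  # minor alleles among 2n parents
            alleles = np.zeros(2 * n)
            alleles[:k] = 1.0
            pairs = alleles.reshape(n, 2).sum(axis=1)
            F[:, l] = pairs
        C = F / 2 + M / 2  # homozygote transmissions only where valid
        C[F == 1] = 0.0  # het father: transmit 0 (still Mendelian)
        return RegionDataset(make_variants(L), [f"t{i}" for i in range(n)], F, M, C)

    def test_threshold_keeps_expected_variants(self):
        ds = self.build([0.10, 0.04, 0.006])
        kept = filter_by_maf(ds, 0.05)
        assert kept.n_variants == 2
        assert [v.variant_id for v in kept.variants] == ["v2", "v3"]

    def test_upper_bound_keeps_all_and_monomorphic_kept(self):
        ds = self.build([0.10, 0.0, 0.006])
        assert filter_by_maf(ds, 0.5).n_variants == 3
        assert "v2" in [v.variant_id for v in filter_by_maf(ds, 0.05).variants]

    def test_empty_result_raises(self):
        ds = self.build([0.2, 0.3])
        with pytest.raises(ValueError, match="no variants pass"):
            filter_by_maf(ds, 0.01)

    def test_composition_equals_min_threshold(self, rng):
        ds = random_trio_dataset(rng, n=40, L=12, freq=0.08, n_controls=10)
        a, b = 0.25, 0.1
        double = filter_by_maf(filter_by_maf(ds, a), b)
        single = filter_by_maf(ds, min(a, b))
        assert [v.variant_id for v in double.variants] == [
            v.variant_id for v in single.variants
        ]
        np.testing.assert_array_equal(double.child, single.child)

    def test_founder_frequencies_pool_controls(self, small_ds):
        # variant 1: parents carry 1+0+0+1 = 2 alleles in 8; controls 1 in 6
        freq = founder_frequencies(small_ds)
        assert freq[0] == pytest.approx(3 / 14)


class TestWriteResults:
    def test_roundtrip_to_six_significant_digits(self, tmp_path, rng):
        ds = random_trio_dataset(rng, n=30, L=5, n_controls=20)
        result = run_conada(
            ds, mode="PC", cfg=SequentialConfig(b_min=50, b_max=200, seed=4)
        )
        out = tmp_path / "res.tsv"
        variant_path = write_results(result, out)
        region = pd.read_csv(out, sep="\t")
        assert region.loc[0, "adjusted_p"] == pytest.approx(
            result.adjusted_p, rel=1e-5
        )
        pv = pd.read_csv(variant_path, sep="\t")
        assert len(pv) == ds.n_variants
        np.testing.assert_allclose(pv["p"], result.per_variant["p"], rtol=1e-5)
        assert {"chrom", "pos", "neg_log10_p"} <= set(pv.columns)
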