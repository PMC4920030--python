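"""Genotype containers and I/O for case-parent trio region data.

A region dataset holds minor-allele genotype scores (0, 1, 2; ``NaN`` for
missing) for ``L`` variant sites across ``n`` case-parent trios (father,
mother, affected child) and, optionally, a panel of unrelated population
controls.  Scores are oriented so that the counted allele is the one that is
*minor among founders* (the trio parents and the controls pooled); ties at
frequency 0.5 keep the allele coding of the source file.

Two on-disk dialects are supported:

* VCF v4.x plus a 6-column PED-style pedigree (FID IID PAT MAT SEX PHENO).
  A row whose PHENO is 2 (affected) and whose PAT/MAT are both non-zero
  defines a trio; a row with PAT = MAT = 0 and PHENO = 1 that is not itself
  referenced as a parent is an unrelated control.  Parents referenced by a
  trio row need no phenotype.
* A TSV genotype matrix (rows = samples, columns = variants, entries
  0/1/2/NA) with the same pedigree format, convenient for tests.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantSite",
    "TrioGenotypes",
    "ControlGenotypes",
    "RegionDataset",
    "load_dataset",
    "check_mendelian",
    "filter_by_maf",
    "founder_frequencies",
    "write_results",
    "write_vcf",
    "write_pedigree",
    "write_genotypes_tsv",
]


@dataclass(frozen=True)
class VariantSite:
    """A biallelic site; ``index`` is its column in the score matrices."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    minor_allele: str
    index: int
    other_allele: str = "A"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class TrioGenotypes:
    """Score vectors for one trio (length L, NaN = missing)."""

    trio_id: str
    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray


@dataclass(frozen=True)
class ControlGenotypes:
    control_ids: tuple[str, ...]
    scores: np.ndarray  # (n_controls, L)


def _mendelian_violation_mask(F: np.ndarray, M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Boolean mask of trio-locus cells where the child score is impossible.

    A parent with score g transmits 1 allele from {1 if g==2} ... {0 if g==0},
    i.e. the child score must lie in [ (f==2)+(m==2), (f>0)+(m>0) ].
    Cells with any missing member are never flagged.
    """
    lo = (F == 2).astype(float) + (M == 2).astype(float)
    hi = (F > 0).astype(float) + (M > 0).astype(float)
    with np.errstate(invalid="ignore"):
        bad = (C < lo) | (C > hi)
    complete = ~(np.isnan(F) | np.isnan(M) | np.isnan(C))
    return bad & complete


@dataclass
class RegionDataset:
    """All genotype scores for one chromosomal region.

    Attributes
    ----------
    variants : list of VariantSite
    trio_ids : list of str
    father, mother, child : (n, L) float arrays of scores, NaN = missing
    controls : (m, L) float array or None
    control_ids : list of str or None
    provenance : dict recording source paths and filters applied
    """

    variants: list[VariantSite]
    trio_ids: list[str]
    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    control_ids: list[str] | None = None
    controls: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.variants)
        n = len(self.trio_ids)
        if n < 1:
            raise ValueError("a RegionDataset needs at least one trio")
        for name in ("father", "mother", "child"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n, L):
                raise ValueError(f"{name} matrix has shape {arr.shape}, expected {(n, L)}")
        if self.controls is not None:
            self.controls = np.asarray(self.controls, dtype=float)
            if self.controls.ndim != 2 or self.controls.shape[1] != L:
                raise ValueError("control matrix column count must equal L")
        idx = [v.index for v in self.variants]
        if idx != list(range(L)):
            raise ValueError("variant indices must be unique and contiguous from 0")

    @property
    def n_trios(self) -> int:
        return len(self.trio_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_controls(self) -> int:
        return 0 if self.controls is None else self.controls.shape[0]

    @property
    def has_controls(self) -> bool:
        return self.controls is not None and self.controls.shape[0] > 0

    def trios(self) -> Iterator[TrioGenotypes]:
        for i, tid in enumerate(self.trio_ids):
            yield TrioGenotypes(tid, self.father[i], self.mother[i], self.child[i])

    def control_panel(self) -> ControlGenotypes:
        if not self.has_controls:
            raise ValueError("dataset has no controls")
        return ControlGenotypes(tuple(self.control_ids or ()), self.controls)

    def with_children(self, child: np.ndarray) -> "RegionDataset":
        """Copy of the dataset with the child score matrix replaced."""
        return RegionDataset(
            variants=self.variants,
            trio_ids=self.trio_ids,
            father=self.father,
            mother=self.mother,
            child=np.asarray(child, dtype=float),
            control_ids=self.control_ids,
            controls=self.controls,
            provenance=dict(self.provenance),
        )


def founder_frequencies(ds: RegionDataset) -> np.ndarray:
    """Allele frequency of the counted allele among founders (parents + controls).

    Missing founder entries are dropped locus-wise.  Loci where every founder
    is missing get frequency 0.
    """
    rows = [ds.father, ds.mother]
    if ds.has_controls:
        rows.append(ds.controls)
    founders = np.vstack(rows)
    counts = np.nansum(founders, axis=0)
    denom = 2.0 * np.sum(~np.isnan(founders), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(denom > 0, counts / np.where(denom > 0, denom, 1.0), 0.0)
    return freq


# ---------------------------------------------------------------------------
# Pedigree handling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _PedPlan:
    trios: list[tuple[str, str, str]]  # (child, father, mother)
    controls: list[str]


def _read_pedigree(path: str | os.PathLike) -> _PedPlan:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"pedigree row has {len(parts)} columns, expected 6: {line!r}")
            rows.append(parts[:6])
    parents_referenced: set[str] = set()
    trios: list[tuple[str, str, str]] = []
    for _fid, iid, pat, mat, _sex, pheno in rows:
        if pat != "0" and mat != "0" and pheno == "2":
            trios.append((iid, pat, mat))
            parents_referenced.update((pat, mat))
    controls = [
        iid
        for _fid, iid, pat, mat, _sex, pheno in rows
        if pat == "0" and mat == "0" and pheno == "1" and iid not in parents_referenced
    ]
    if not trios:
        raise ValueError("pedigree defines no trios (affected child with both parents)")
    return _PedPlan(trios=trios, controls=controls)


# ---------------------------------------------------------------------------
# Genotype sources
# ---------------------------------------------------------------------------


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        raise ValueError(f"region must look like 'chr:start-end', got {region!r}")
    start_s, _, end_s = span.partition("-")
    return chrom, int(start_s), int(end_s)


def _load_vcf_matrix(
    path: str | os.PathLike,
    region: str | None,
    split_multiallelic: bool,
) -> tuple[list[str], pd.DataFrame, np.ndarray]:
    """Returns (sample ids, variant table, samples x L ALT-count matrix)."""
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    want = _parse_region(region) if region else None
    meta_rows = []
    columns = []
    for variant in vcf:
        if want is not None:
            chrom, start, end = want
            if variant.CHROM != chrom or not (start <= variant.POS <= end):
                continue
        alts = variant.ALT
        if len(alts) != 1 and not split_multiallelic:
            raise ValueError(
                f"multi-allelic site {variant.CHROM}:{variant.POS} "
                "(pass split_multiallelic=True to decompose)"
            )
        gts = variant.genotypes  # [[a0, a1, phased], ...]
        for k, alt in enumerate(alts, start=1):
            scores = np.full(len(samples), np.nan)
            for s, gt in enumerate(gts):
                alleles = gt[:-1]
                if len(alleles) != 2:
                    warnings.warn(
                        f"non-diploid genotype for sample {samples[s]} at "
                        f"{variant.CHROM}:{variant.POS}; treated as missing"
                    )
                    continue
                if alleles[0] < 0 or alleles[1] < 0:
                    if alleles[0] >= 0 or alleles[1] >= 0:
                        warnings.warn(
                            f"half-missing genotype for sample {samples[s]} at "
                            f"{variant.CHROM}:{variant.POS}; treated as missing"
                        )
                    continue
                scores[s] = int(alleles[0] == k) + int(alleles[1] == k)
            vid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
            if len(alts) > 1:
                vid = f"{vid}:{alt}"
            meta_rows.append(
                {"variant_id": vid, "chrom": variant.CHROM, "pos": variant.POS,
                 "ref": variant.REF, "alt": alt}
            )
            columns.append(scores)
    if not columns:
        raise ValueError("no variants found in the requested region")
    meta = pd.DataFrame(meta_rows)
    matrix = np.column_stack(columns)
    return samples, meta, matrix


def _load_tsv_matrix(path: str | os.PathLike) -> tuple[list[str], pd.DataFrame, np.ndarray]:
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "."])
    samples = [str(s) for s in table.index]
    meta = pd.DataFrame(
        {
            "variant_id": [str(c) for c in table.columns],
            "chrom": "0",
            "pos": np.arange(1, table.shape[1] + 1),
            "ref": "A",
            "alt": "C",
        }
    )
    matrix = table.to_numpy(dtype=float)
    bad = matrix[~np.isnan(matrix)]
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        raise ValueError("TSV genotype entries must be 0, 1, 2 or NA")
    return samples, meta, matrix


def load_dataset(
    genotype_source: str | os.PathLike,
    pedigree: str | os.PathLike,
    region: str | None = None,
    *,
    split_multiallelic: bool = False,
    mendelian_policy: str = "error",
) -> RegionDataset:
    """Load a region dataset from a VCF (or TSV matrix) plus a pedigree file.

    Scores are re-oriented to count the founder-minor allele.  Mendelian
    inconsistencies raise by default; ``mendelian_policy='set-missing'``
    converts the offending trio-locus to missing instead.
    """
    if mendelian_policy not in ("error", "set-missing"):
        raise ValueError(f"unknown mendelian_policy {mendelian_policy!r}")
    src = os.fspath(genotype_source)
    if src.endswith((".tsv", ".txt")):
        samples, meta, matrix = _load_tsv_matrix(src)
        if region is not None:
            raise ValueError("region filtering is not supported for the TSV dialect")
    else:
        samples, meta, matrix = _load_vcf_matrix(src, region, split_multiallelic)
    plan = _read_pedigree(pedigree)
    index = {s: i for i, s in enumerate(samples)}
    needed = [iid for trio in plan.trios for iid in trio] + plan.controls
    for iid in needed:
        if iid not in index:
            raise ValueError(f"sample not found in genotype source: {iid}")

    child_rows = matrix[[index[c] for c, _f, _m in plan.trios]]
    father_rows = matrix[[index[f] for _c, f, _m in plan.trios]]
    mother_rows = matrix[[index[m] for _c, _f, m in plan.trios]]
    controls = matrix[[index[s] for s in plan.controls]] if plan.controls else None

    # Orient scores to the founder-minor allele (ties keep the source coding).
    founders = [father_rows, mother_rows] + ([controls] if controls is not None else [])
    stacked = np.vstack(founders)
    counts = np.nansum(stacked, axis=0)
    denom = 2.0 * np.sum(~np.isnan(stacked), axis=0)
    freq = np.where(denom > 0, counts / np.where(denom > 0, denom, 1.0), 0.0)
    flip = freq > 0.5
    for arr in (child_rows, father_rows, mother_rows) + ((controls,) if controls is not None else ()):
        arr[:, flip] = 2.0 - arr[:, flip]

    variants = [
        VariantSite(
            variant_id=row.variant_id,
            chrom=str(row.chrom),
            pos=int(row.pos),
            minor_allele=(row.ref if flip[i] else row.alt),
            other_allele=(row.alt if flip[i] else row.ref),
            index=i,
        )
        for i, row in enumerate(meta.itertuples())
    ]
    ds = RegionDataset(
        variants=variants,
        trio_ids=[c for c, _f, _m in plan.trios],
        father=father_rows,
        mother=mother_rows,
        child=child_rows,
        control_ids=list(plan.controls) if plan.controls else None,
        controls=controls,
        provenance={
            "genotype_source": src,
            "pedigree": os.fspath(pedigree),
            "region": region,
            "filters": [],
        },
    )
    bad = _mendelian_violation_mask(ds.father, ds.mother, ds.child)
    if bad.any():
        if mendelian_policy == "error":
            i, l = np.argwhere(bad)[0]
            raise ValueError(
                f"Mendelian inconsistency: trio {ds.trio_ids[i]} at "
                f"{ds.variants[l].variant_id} (use mendelian_policy='set-missing' to mask)"
            )
        ds.child[bad] = np.nan
        ds.provenance["filters"].append(f"mendelian-set-missing:{int(bad.sum())}")
    return ds


def check_mendelian(ds: RegionDataset) -> list[tuple[str, str]]:
    """All (trio_id, variant_id) pairs whose child score is impossible."""
    bad = _mendelian_violation_mask(ds.father, ds.mother, ds.child)
    return [
        (ds.trio_ids[i], ds.variants[l].variant_id) for i, l in np.argwhere(bad)
    ]


def filter_by_maf(ds: RegionDataset, max_maf: float) -> RegionDataset:
    """Keep variants whose founder (parents + controls) frequency is <= max_maf."""
    if not (0 < max_maf <= 0.5):
        raise ValueError("max_maf must be in (0, 0.5]")
    freq = founder_frequencies(ds)
    keep = np.flatnonzero(freq <= max_maf)
    if keep.size == 0:
        raise ValueError(f"no variants pass MAF filter at {max_maf}")
    variants = [
        VariantSite(
            variant_id=v.variant_id,
            chrom=v.chrom,
            pos=v.pos,
            minor_allele=v.minor_allele,
            other_allele=v.other_allele,
            index=j,
        )
        for j, v in enumerate(ds.variants[k] for k in keep)
    ]
    prov = dict(ds.provenance)
    prov["filters"] = list(prov.get("filters", [])) + [f"maf<={max_maf}"]
    return RegionDataset(
        variants=variants,
        trio_ids=ds.trio_ids,
        father=ds.father[:, keep],
        mother=ds.mother[:, keep],
        child=ds.child[:, keep],
        control_ids=ds.control_ids,
        controls=None if ds.controls is None else ds.controls[:, keep],
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_results(result, path: str | os.PathLike, region_id: str = "region") -> str:
    """Write a region-level TSV and a companion per-variant TSV.

    The per-variant table (``<path stem>.variants.tsv``) carries Manhattan-ready
    columns (chrom, pos, -log10 P) along with each variant's P-value and weight.
    Returns the per-variant path.
    """
    path = os.fspath(path)
    region_row = pd.DataFrame(
        [
            {
                "region": region_id,
                "mode": result.mode,
                "adjusted_p": result.adjusted_p,
                "neg_log10_adjusted_p": -math.log10(result.adjusted_p),
                "min_p": result.minp_obs,
                "best_theta": result.best_theta,
                "b_used": result.b_used,
                "stopped_early": result.stopped_early,
                "n_variants": len(result.per_variant),
                "seed": result.seed,
            }
        ]
    )
    region_row.to_csv(path, sep="\t", index=False, float_format="%.6g")
    stem, _ext = os.path.splitext(path)
    variant_path = stem + ".variants.tsv"
    pv = result.per_variant.copy()
    with np.errstate(divide="ignore"):
        pv["neg_log10_p"] = -np.log10(pv["p"])
    pv.to_csv(variant_path, sep="\t", index=False, float_format="%.6g")
    return variant_path


def _score_to_gt(score: float) -> str:
    if np.isnan(score):
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(score)]


def write_vcf(ds: RegionDataset, path: str | os.PathLike) -> None:
    """Emit the dataset as a minimal VCF v4.2 (GT only).

    REF is the non-counted allele and ALT the counted (minor) allele, so a
    round-trip through :func:`load_dataset` preserves scores.
    """
    sample_ids = (
        [f"{t}_fa" for t in ds.trio_ids]
        + [f"{t}_mo" for t in ds.trio_ids]
        + list(ds.trio_ids)
        + list(ds.control_ids or [])
    )
    matrices = [ds.father, ds.mother, ds.child] + (
        [ds.controls] if ds.has_controls else []
    )
    allmat = np.vstack(matrices)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in ds.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for v in ds.variants:
            gts = "\t".join(_score_to_gt(allmat[s, v.index]) for s in range(allmat.shape[0]))
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.other_allele}\t"
                f"{v.minor_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_pedigree(ds: RegionDataset, path: str | os.PathLike) -> None:
    """6-column PED companion: trio parents, affected children, unaffected controls."""
    with open(path, "w") as fh:
        for t in ds.trio_ids:
            fh.write(f"{t}\t{t}_fa\t0\t0\t1\t0\n")
            fh.write(f"{t}\t{t}_mo\t0\t0\t2\t0\n")
            fh.write(f"{t}\t{t}\t{t}_fa\t{t}_mo\t0\t2\n")
        for c in ds.control_ids or []:
            fh.write(f"{c}\t{c}\t0\t0\t0\t1\n")


def write_genotypes_tsv(ds: RegionDataset, path: str | os.PathLike) -> None:
    """Emit the TSV dialect (rows = samples, cols = variants, entries 0/1/2/NA)."""
    sample_ids = (
        [f"{t}_fa" for t in ds.trio_ids]
        + [f"{t}_mo" for t in ds.trio_ids]
        + list(ds.trio_ids)
        + list(ds.control_ids or [])
    )
    matrices = [ds.father, ds.mother, ds.child] + (
        [ds.controls] if ds.has_controls else []
    )
    table = pd.DataFrame(
        np.vstack(matrices),
        index=pd.Index(sample_ids, name="sample"),
        columns=[v.variant_id for v in ds.variants],
    )
    table.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")
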