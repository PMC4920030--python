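"""Per-variant weights for the combined significance score.

Two schemes are provided:

* MAF weighting — w_l = Beta(MAF_l; 1, 25) = 25 (1 - MAF_l)^24, the density of
  a Beta(1, 25) at the variant frequency computed from trio parents.  This is
  the standard rare-variant up-weighting used by SKAT/SKAT-O and related
  region tests; it decays quickly, giving rare variants most of the mass.
* PC (population-control) weighting — the Cochran-Armitage trend chi-square
  comparing trio parents against unrelated controls on the 2 x 3 genotype
  table with scores (0, 1, 2).  Loci whose genotype distributions differ
  between parents and controls receive large weights.  The square-root (Z
  magnitude) variant is available via ``statistic='z'``.

Both schemes depend only on parents and controls, never on children, so
weight vectors are invariant under the transmission-flip permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import RegionDataset

__all__ = [
    "GenotypeCountsTable",
    "WeightVector",
    "parental_maf",
    "maf_weights",
    "genotype_counts",
    "trend_chi_square",
    "pc_weights",
]


@dataclass(frozen=True)
class WeightVector:
    values: np.ndarray
    scheme: str  # "MAF" or "PC"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("weights must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GenotypeCountsTable:
    """2 x 3 genotype counts: controls (r) vs trio parents (s), scores 0/1/2."""

    r: tuple[int, int, int]
    s: tuple[int, int, int]

    @property
    def n_controls(self) -> int:
        return sum(self.r)

    @property
    def n_parents(self) -> int:
        return sum(self.s)

    @property
    def column_totals(self) -> tuple[int, int, int]:
        return tuple(ri + si for ri, si in zip(self.r, self.s))

    @property
    def total(self) -> int:
        return self.n_controls + self.n_parents


def parental_maf(ds: RegionDataset) -> np.ndarray:
    """Variant frequency from trio parents: (sum f + sum m) / (4 x complete trios).

    A trio counts at a locus only when both parents are non-missing there.
    Loci with no complete parent pair get frequency 0 with a warning.
    """
    ok = ~(np.isnan(ds.father) | np.isnan(ds.mother))
    counts = np.where(ok, ds.father + ds.mother, 0.0).sum(axis=0)
    denom = 4.0 * ok.sum(axis=0)
    if np.any(denom == 0):
        warnings.warn("some loci have no complete parent pair; their MAF is set to 0")
    return np.where(denom > 0, counts / np.where(denom > 0, denom, 1.0), 0.0)


def maf_weights(maf: np.ndarray) -> WeightVector:
    """Beta(1, 25) density at each frequency: w = 25 (1 - MAF)^24."""
    maf = np.asarray(maf, dtype=float)
    if np.any((maf < 0) | (maf > 1)):
        raise ValueError("MAF entries must lie in [0, 1]")
    return WeightVector(values=25.0 * (1.0 - maf) ** 24, scheme="MAF")


def genotype_counts(ds: RegionDataset, l: int) -> GenotypeCountsTable:
    """Tally controls and trio parents by genotype score at locus l.

    Each parent is counted once per trio (a duplicated individual appearing in
    two trios is counted twice); missing entries are excluded.
    """
    if not ds.has_controls:
        raise ValueError("PC weighting requires controls")
    parents = np.concatenate([ds.father[:, l], ds.mother[:, l]])
    controls = ds.controls[:, l]
    s = tuple(int(np.sum(parents == g)) for g in (0, 1, 2))
    r = tuple(int(np.sum(controls == g)) for g in (0, 1, 2))
    return GenotypeCountsTable(r=r, s=s)


def trend_chi_square(table: GenotypeCountsTable) -> float:
    """Cochran-Armitage trend chi-square with scores (0, 1, 2).

    With A = s1 + 2 s2, B = N1 + 2 N2, C = N1 + 4 N2:

        w = N (N A - N_s B)^2 / [ N_s (N - N_s) (N C - B^2) ]

    Returns 0 when the denominator vanishes (monomorphic pooled sample or a
    group absent).
    """
    n_s = table.n_parents
    n = table.total
    n0, n1, n2 = table.column_totals
    a = table.s[1] + 2 * table.s[2]
    b = n1 + 2 * n2
    c = n1 + 4 * n2
    denom = n_s * (n - n_s) * (n * c - b * b)
    if denom == 0:
        return 0.0
    return n * (n * a - n_s * b) ** 2 / denom


def pc_weights(ds: RegionDataset, statistic: str = "chisq") -> WeightVector:
    """Armitage-trend weights comparing trio parents vs population controls.

    ``statistic='chisq'`` (default) uses the trend chi-square itself;
    ``'z'`` uses its square root.
    """
    if statistic not in ("chisq", "z"):
        raise ValueError(f"unknown statistic {statistic!r}")
    values = np.array(
        [trend_chi_square(genotype_counts(ds, l)) for l in range(ds.n_variants)]
    )
    if statistic == "z":
        values = np.sqrt(values)
    return WeightVector(values=values, scheme="PC")
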