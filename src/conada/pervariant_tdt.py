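"""Per-variant score test conditional on parental genotypes.

For variant l, each trio i contributes the deviation of the child's genotype
score from its Mendelian expectation given the parents,

    d_il = c_il - e(c_il),     e(c_il) = (f_il + m_il) / 2,

with conditional variance Var(c_il | parents) = f(2-f)/4 + m(2-m)/4, i.e.
0.25 per heterozygous parent.  The region statistic

    T_l = (sum_i d_il)^2 / sum_i Var(c_il | parents)

is asymptotically chi-square with 1 df under the null of no association, and
restricted to heterozygous parents it reduces to the classic transmission
disequilibrium test (b - c)^2 / (b + c).  Because inference is conditional on
parental genotypes, T_l is unaffected by population stratification.

Trio-locus cells with any missing member contribute nothing.  Loci with no
informative (heterozygous) parent get T = 0 and P = 1 rather than being
dropped, keeping the locus axis aligned with the weight vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import RegionDataset

__all__ = [
    "TransmissionSummary",
    "expected_score",
    "conditional_variance",
    "transmission_summary",
    "variant_statistic",
    "variant_pvalues",
    "trio_contributions",
    "pvalues_from_deviations",
]


def expected_score(f, m):
    """Expected child score given parental scores: (f + m) / 2 (NaN propagates)."""
    f = np.asarray(f, dtype=float)
    m = np.asarray(m, dtype=float)
    return (f + m) / 2.0


def conditional_variance(f, m):
    """Variance of the child score given parents: 0.25 per heterozygous parent."""
    f = np.asarray(f, dtype=float)
    m = np.asarray(m, dtype=float)
    return f * (2.0 - f) / 4.0 + m * (2.0 - m) / 4.0


@dataclass(frozen=True)
class TransmissionSummary:
    """Per-variant aggregates over trios (missing cells excluded).

    deviation : sum_i (c_il - e_il), length L
    variance : sum_i Var(c_il | parents), length L; equals informative/4
    informative : number of heterozygous parents contributing, length L
    """

    deviation: np.ndarray
    variance: np.ndarray
    informative: np.ndarray


def trio_contributions(ds: RegionDataset) -> tuple[np.ndarray, np.ndarray]:
    """(n, L) per-trio deviation matrix (missing cells zeroed) and length-L variance.

    The deviation matrix is the only quantity that changes under the
    transmission-flip null, which is why the permutation engine consumes it
    directly: flipping trio i negates row i.
    """
    complete = ~(np.isnan(ds.father) | np.isnan(ds.mother) | np.isnan(ds.child))
    e = expected_score(ds.father, ds.mother)
    dev = np.where(complete, ds.child - e, 0.0)
    var = np.where(complete, conditional_variance(ds.father, ds.mother), 0.0).sum(axis=0)
    return dev, var


def transmission_summary(ds: RegionDataset) -> TransmissionSummary:
    complete = ~(np.isnan(ds.father) | np.isnan(ds.mother) | np.isnan(ds.child))
    dev, var = trio_contributions(ds)
    het = np.where(complete, (ds.father == 1).astype(float) + (ds.mother == 1), 0.0)
    return TransmissionSummary(
        deviation=dev.sum(axis=0),
        variance=var,
        informative=het.sum(axis=0).astype(int),
    )


def variant_statistic(ds: RegionDataset, l: int) -> float:
    """T_l = d_l^2 / v_l; 0 when no parent is informative at l."""
    summ = transmission_summary(ds)
    if summ.variance[l] == 0:
        return 0.0
    return float(summ.deviation[l] ** 2 / summ.variance[l])


def pvalues_from_deviations(dev_sum: np.ndarray, variance: np.ndarray) -> np.ndarray:
    """Chi-square(1) upper-tail P-values from per-variant deviation sums.

    Vectorised over leading axes of ``dev_sum`` (e.g. one row per permutation).
    Zero-variance loci get P = 1.
    """
    variance = np.asarray(variance, dtype=float)
    ok = variance > 0
    T = np.zeros(np.broadcast_shapes(np.shape(dev_sum), variance.shape))
    np.divide(np.square(dev_sum), variance, out=T, where=ok)
    p = stats.chi2.sf(T, df=1)
    return np.where(ok, p, 1.0)


def variant_pvalues(ds: RegionDataset) -> np.ndarray:
    """P-values p_1..p_L of the conditional score statistic at every locus."""
    summ = transmission_summary(ds)
    return pvalues_from_deviations(summ.deviation, summ.variance)
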