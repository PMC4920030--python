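"""Truncated weighted Fisher combination over a grid of truncation thresholds.

For each candidate truncation threshold theta_j, the per-variant P-values are
combined into a significance score

    S_j = sum_l  w_l * (-ln p_l) * I[p_l <= theta_j],

so that only variants significant at theta_j contribute.  Because the best
threshold is unknown a priori, S_j is computed on the observed data and on
every permuted replicate; each column of the resulting score matrix is
converted to rank-based P-values, the minimum across thresholds (MinP) is
taken per row, and the observed MinP is referred to the permutation MinP
distribution to give a single adjusted P-value that accounts for the
threshold search (single-layer Westfall-Young min-P).

All rank P-values use inclusive ties and include the evaluated row in its own
denominator, so no Monte Carlo P-value can be zero.  Rank P-values, MinP and
the adjusted P are invariant to rescaling all weights by a positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weights import WeightVector

__all__ = [
    "ThresholdGrid",
    "ScoreMatrix",
    "ConadaResult",
    "significance_scores",
    "score_rows",
    "rank_pvalues",
    "min_p",
    "adjusted_pvalue",
]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing candidate truncation thresholds in (0, 1).

    The default grid is 0.10, 0.11, ..., 0.20 (11 thresholds); ``wide21``
    gives the broader 0.05..0.25 grid, which behaves nearly identically.
    """

    thetas: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.10, 0.201, 0.01), 10)
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.thetas, dtype=float)
        object.__setattr__(self, "thetas", t)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("threshold grid must be a non-empty vector")
        if not (np.all(np.diff(t) > 0) and t[0] > 0 and t[-1] < 1):
            raise ValueError("thresholds must be strictly increasing within (0, 1)")

    @classmethod
    def default11(cls) -> "ThresholdGrid":
        return cls()

    @classmethod
    def wide21(cls) -> "ThresholdGrid":
        return cls(np.round(np.arange(0.05, 0.251, 0.01), 10))

    @classmethod
    def from_string(cls, text: str) -> "ThresholdGrid":
        """Parse a 'start:stop:step' specification, e.g. '0.10:0.20:0.01'."""
        start, stop, step = (float(x) for x in text.split(":"))
        return cls(np.round(np.arange(start, stop + step / 2, step), 10))

    def __len__(self) -> int:
        return len(self.thetas)


def _clamped_neglog(pvals: np.ndarray) -> np.ndarray:
    pvals = np.asarray(pvals, dtype=float)
    if np.any(pvals <= 0):
        warnings.warn("P-values of 0 clamped to the smallest positive float")
        pvals = np.maximum(pvals, _TINY)
    return -np.log(pvals), pvals


def score_rows(pmatrix: np.ndarray, weights: np.ndarray, grid: ThresholdGrid) -> np.ndarray:
    """Significance scores for a stack of P-value rows: (R, L) -> (R, J)."""
    neglog, pmatrix = _clamped_neglog(pmatrix)
    contrib = neglog * np.asarray(weights, dtype=float)  # (R, L)
    inside = pmatrix[..., None] <= grid.thetas  # (R, L, J)
    return np.einsum("...l,...lj->...j", contrib, inside)


def significance_scores(
    pvals: np.ndarray, weights: WeightVector | np.ndarray, grid: ThresholdGrid
) -> np.ndarray:
    """S_j = sum_l w_l (-ln p_l) I[p_l <= theta_j], length J; non-decreasing in j."""
    w = weights.values if isinstance(weights, WeightVector) else np.asarray(weights)
    pvals = np.atleast_1d(np.asarray(pvals, dtype=float))
    if pvals.shape[-1] != len(w):
        raise ValueError("pvals and weights must have equal length")
    return score_rows(pvals, w, grid)


def rank_pvalues(S: np.ndarray) -> np.ndarray:
    """Column-wise inclusive rank P-values of an (R, J) score matrix.

    P_rj = #{r' : S_r'j >= S_rj} / R, counting row r itself, so each entry
    lies in (0, 1].  Row 0 is conventionally the observed sample.
    """
    S = np.asarray(S, dtype=float)
    R = S.shape[0]
    P = np.empty_like(S)
    for j in range(S.shape[1]):
        col = S[:, j]
        order = np.sort(col)
        count_ge = R - np.searchsorted(order, col, side="left")
        P[:, j] = count_ge / R
    return P


def min_p(P: np.ndarray) -> np.ndarray:
    """Row-wise minimum rank P-value across the threshold grid."""
    return np.asarray(P, dtype=float).min(axis=1)


def adjusted_pvalue(minp_obs: float, minp_perms: np.ndarray) -> float:
    """(1 + #{b : MinP^(b) <= MinP_obs}) / (B + 1) — add-one Monte Carlo P."""
    minp_perms = np.asarray(minp_perms, dtype=float)
    B = len(minp_perms)
    if B < 1:
        raise ValueError("need at least one permutation")
    return float((1 + np.sum(minp_perms <= minp_obs)) / (B + 1))


@dataclass(frozen=True)
class ScoreMatrix:
    """Scores, rank P-values and MinP for the observed row plus B permutations."""

    S: np.ndarray  # (B+1, J); row 0 = observed
    grid: ThresholdGrid
    P: np.ndarray = field(init=False)
    minp: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] < 2:
            raise ValueError("score matrix needs the observed row plus >= 1 permutation")
        object.__setattr__(self, "S", S)
        P = rank_pvalues(S)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "minp", min_p(P))

    @property
    def n_permutations(self) -> int:
        return self.S.shape[0] - 1

    def observed_adjusted_p(self) -> float:
        return adjusted_pvalue(self.minp[0], self.minp[1:])


@dataclass(frozen=True)
class ConadaResult:
    """Outcome of one region-level test.

    adjusted_p : permutation-adjusted P-value of the region
    b_used : permutations consumed before stopping
    stopped_early : whether the sequential rule stopped before B_max
    minp_obs : observed minimum rank P-value across thresholds
    best_theta : threshold achieving the observed MinP (smallest on ties)
    per_threshold : DataFrame (theta, score, rank_p)
    per_variant : DataFrame (variant_id, chrom, pos, p, weight)
    mode : "MAF" or "PC"
    seed : permutation seed
    """

    adjusted_p: float
    b_used: int
    stopped_early: bool
    minp_obs: float
    best_theta: float
    per_threshold: pd.DataFrame
    per_variant: pd.DataFrame
    mode: str
    seed: int

    def __post_init__(self) -> None:
        if not (0 < self.adjusted_p <= 1):
            raise ValueError("adjusted_p must lie in (0, 1]")
        if self.adjusted_p < 1.0 / (self.b_used + 1) - 1e-12:
            raise ValueError("adjusted_p below the Monte Carlo resolution 1/(B+1)")
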