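"""Synthetic stratified trio + control studies for calibration and power work.

The generator emulates a two-subpopulation exome-region study: a
"EUR-like" subpopulation with higher disease prevalence (default 0.05) and a
more genetically diverse "AFR-like" subpopulation with lower prevalence
(default 0.01).  Site frequencies differentiate between the subpopulations by
a Balding-Nichols construction around a shared ancestral rare-variant
spectrum, and each subpopulation is represented by a finite pool of binary
haplotypes.  Sampling individuals as random haplotype pairs from a finite
pool induces within-region linkage disequilibrium; this founder-pool scheme
stands in for coalescent sequence simulation and reproduces the statistical
structure the region test depends on (stratified frequencies, a rare
spectrum, pool-induced LD) without modelling real human LD maps.

Disease risk is logistic in the genotype-score vector G,

    P(affected | G) = expit(logit(K_subpop) + beta . G),

with per-locus effects calibrated from a population attributable fraction
(PAF) eta via the relative-risk inversion beta = ln(1 + eta / ((1-eta) MAF)).
Case-parent trios are ascertained by rejection sampling on an affected child;
controls are unrelated individuals ascertained unaffected (switchable to
purely random population draws).

Defaults mirror the reference study design: 500 trios plus 500 controls,
causal variants drawn from sites with pooled MAF <= 0.01 (25% or 75% of
them), per-locus PAF 0.01 (all deleterious) or 0.02 (half protective), and an
analysis marker set capped at pooled MAF <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .core_data import RegionDataset, VariantSite

__all__ = [
    "PopulationModel",
    "FounderPools",
    "DiseaseModel",
    "StudyDesign",
    "StudyTruth",
    "build_founder_pools",
    "paf_to_beta",
    "disease_probability",
    "sample_trio",
    "sample_control",
    "generate_study",
    "sample_population",
]

SUBPOPULATIONS = ("EUR", "AFR")


@dataclass(frozen=True)
class PopulationModel:
    """Region and subpopulation-differentiation parameters.

    ``n_sites`` defaults to 87, the typical analysis-region size in exome
    capture regions of a few kb.  ``fst`` (default 0.10) is the
    Balding-Nichols differentiation between the two subpopulations.  The
    ancestral spectrum is Beta(0.15, 2) truncated to (0, ``max_ancestral_freq``],
    putting most sites below 1% frequency.  Explicit per-subpopulation
    frequencies (a (2, L) array) override the random spectrum.
    """

    n_sites: int = 87
    pool_size: int = 2000
    fst: float = 0.10
    ancestral_alpha: float = 0.15
    ancestral_beta: float = 2.0
    max_ancestral_freq: float = 0.05
    frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frequencies is not None:
            f = np.asarray(self.frequencies, dtype=float)
            if f.shape != (2, self.n_sites):
                raise ValueError("explicit frequencies must have shape (2, n_sites)")
            if np.any((f < 0) | (f > 1)):
                raise ValueError("frequencies must lie in [0, 1]")
            object.__setattr__(self, "frequencies", f)
        if not (0 <= self.fst < 1):
            raise ValueError("fst must lie in [0, 1)")


@dataclass(frozen=True)
class FounderPools:
    """Binary haplotype pools, one per subpopulation: each (H, L) uint8."""

    haplotypes: tuple[np.ndarray, np.ndarray]
    subpop_frequencies: np.ndarray  # (2, L) drawn frequencies

    @property
    def n_sites(self) -> int:
        return self.haplotypes[0].shape[1]

    def pooled_frequency(self) -> np.ndarray:
        """Empirical frequency in the equally pooled two-subpopulation sample."""
        return np.concatenate(self.haplotypes).mean(axis=0)


def build_founder_pools(pm: PopulationModel, rng: np.random.Generator) -> FounderPools:
    """Draw subpopulation frequencies (Balding-Nichols) and fill the pools.

    With differentiation F, each subpopulation frequency is drawn as
    Beta(p (1-F)/F, (1-p)(1-F)/F) around the ancestral p; F = 0 gives both
    subpopulations exactly the ancestral frequency.  Haplotype sites are
    independent Bernoulli draws; LD arises downstream from resampling the
    finite pool.
    """
    if pm.frequencies is not None:
        freqs = pm.frequencies
    else:
        anc = np.empty(pm.n_sites)
        filled = 0
        while filled < pm.n_sites:
            draw = rng.beta(pm.ancestral_alpha, pm.ancestral_beta, size=pm.n_sites)
            ok = (draw > 0) & (draw <= pm.max_ancestral_freq)
            take = min(ok.sum(), pm.n_sites - filled)
            anc[filled : filled + take] = draw[ok][:take]
            filled += take
        if pm.fst == 0:
            freqs = np.vstack([anc, anc])
        else:
            k = (1.0 - pm.fst) / pm.fst
            freqs = rng.beta(anc * k, (1.0 - anc) * k, size=(2, pm.n_sites))
    pools = tuple(
        (rng.random((pm.pool_size, pm.n_sites)) < freqs[s]).astype(np.uint8)
        for s in range(2)
    )
    return FounderPools(haplotypes=pools, subpop_frequencies=np.asarray(freqs))


def paf_to_beta(eta: float, maf: float | np.ndarray) -> float | np.ndarray:
    """Per-allele log relative risk implied by a population attributable fraction.

    Inverting PAF = f (RR - 1) / [1 + f (RR - 1)] with exposure frequency
    f = MAF gives beta = ln RR = ln(1 + eta / ((1 - eta) MAF)).  Loci with
    MAF = 0 are unobservable and get beta = 0 with a warning.
    """
    if not (0 <= eta < 1):
        raise ValueError("eta must lie in [0, 1)")
    maf_arr = np.asarray(maf, dtype=float)
    if np.any(maf_arr < 0) or np.any(maf_arr > 1):
        raise ValueError("maf must lie in [0, 1]")
    zero = maf_arr == 0
    if np.any(zero) and eta > 0:
        warnings.warn("PAF requested at MAF = 0; effect set to 0 (unobservable locus)")
    safe = np.where(zero, 1.0, maf_arr)
    beta = np.log1p(eta / ((1.0 - eta) * safe))
    beta = np.where(zero, 0.0, beta)
    return float(beta) if np.isscalar(maf) else beta


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease model: P(affected) = expit(logit(K_subpop) + beta . G)."""

    beta: np.ndarray
    prevalence: tuple[float, float] = (0.05, 0.01)  # (EUR-like, AFR-like)
    causal_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "beta", b)
        object.__setattr__(
            self, "causal_indices", np.asarray(self.causal_indices, dtype=int)
        )
        noncausal = np.setdiff1d(np.arange(len(b)), self.causal_indices)
        if np.any(b[noncausal] != 0):
            raise ValueError("beta must be 0 at non-causal loci")

    @classmethod
    def null(cls, n_sites: int, prevalence=(0.05, 0.01)) -> "DiseaseModel":
        return cls(beta=np.zeros(n_sites), prevalence=prevalence)

    @property
    def intercepts(self) -> np.ndarray:
        return logit(np.asarray(self.prevalence))


def disease_probability(G: np.ndarray, subpop, dm: DiseaseModel):
    """Disease probability for genotype-score vector(s) G given subpopulation labels."""
    G_arr = np.asarray(G, dtype=float)
    scalar = G_arr.ndim == 1 and np.ndim(subpop) == 0
    eta = dm.intercepts[np.atleast_1d(subpop).astype(int)] + np.atleast_2d(G_arr) @ dm.beta
    out = expit(eta)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of one synthetic study.

    Mixtures are (EUR-like, AFR-like) probabilities for the source population
    of trios and of controls.  ``causal_fraction`` applies to sites with
    pooled founder MAF <= ``rare_maf``; ``deleterious_fraction`` of the causal
    set gets positive effects, the rest negative.  ``paf`` is the per-locus
    population attributable fraction used to size effects.
    """

    n_trios: int = 500
    n_controls: int = 500
    trio_mixture: tuple[float, float] = (0.5, 0.5)
    control_mixture: tuple[float, float] = (0.5, 0.5)
    causal_fraction: float = 0.25
    deleterious_fraction: float = 1.0
    paf: float = 0.01
    rare_maf: float = 0.01
    max_maf: float = 0.05
    controls: str = "unaffected"  # or "random"
    paf_exposure: str = "allele"  # or "carrier"

    def __post_init__(self) -> None:
        for mix in (self.trio_mixture, self.control_mixture):
            if abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise ValueError("mixtures must be non-negative and sum to 1")
        for frac in (self.causal_fraction, self.deleterious_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.controls not in ("unaffected", "random"):
            raise ValueError("controls must be 'unaffected' or 'random'")
        if self.paf_exposure not in ("allele", "carrier"):
            raise ValueError("paf_exposure must be 'allele' or 'carrier'")


@dataclass(frozen=True)
class StudyTruth:
    """Ground truth of a generated study (pre-filter locus indexing)."""

    causal_indices: np.ndarray
    beta: np.ndarray
    pooled_maf: np.ndarray
    kept_indices: np.ndarray  # loci surviving the analysis MAF cap
    seed: int
    trio_acceptance_rate: float
    control_acceptance_rate: float


_MIN_ACCEPTANCE = 1e-6


def _draw_subpops(mixture, size: int, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(size) >= mixture[0]).astype(int)  # 0 = EUR-like, 1 = AFR-like


def _sample_trios_batch(pools: FounderPools, dm: DiseaseModel, mixture, size, rng):
    """Candidate trios: parental scores, child scores, subpop, affected flag."""
    sub = _draw_subpops(mixture, size, rng)
    L = pools.n_sites
    fat = np.empty((size, L))
    mot = np.empty((size, L))
    chi = np.empty((size, L))
    for s in range(2):
        idx = np.flatnonzero(sub == s)
        if idx.size == 0:
            continue
        pool = pools.haplotypes[s]
        H = pool.shape[0]
        hap_idx = rng.integers(0, H, size=(idx.size, 4))  # father h1,h2; mother h1,h2
        f1, f2 = pool[hap_idx[:, 0]], pool[hap_idx[:, 1]]
        m1, m2 = pool[hap_idx[:, 2]], pool[hap_idx[:, 3]]
        fat[idx] = f1 + f2
        mot[idx] = m1 + m2
        tf = rng.integers(0, 2, size=idx.size)[:, None]  # transmitted haplotype choice
        tm = rng.integers(0, 2, size=idx.size)[:, None]
        chi[idx] = np.where(tf == 0, f1, f2) + np.where(tm == 0, m1, m2)
    affected = rng.random(size) < disease_probability(chi, sub, dm)
    return fat, mot, chi, sub, affected


def _rejection_sample(draw_batch, accept_col, n_needed: int, rng: np.random.Generator):
    """Generic batched rejection sampler; returns stacked accepted arrays."""
    out = None
    drawn = accepted = 0
    while accepted < n_needed:
        size = max(256, 4 * (n_needed - accepted))
        batch = draw_batch(size, rng)
        keep = batch[accept_col]
        drawn += size
        accepted += int(keep.sum())
        picked = tuple(arr[keep] for arr in batch[:accept_col])
        out = picked if out is None else tuple(
            np.concatenate([a, b]) for a, b in zip(out, picked)
        )
        if drawn >= 1_000_000 and accepted < drawn * _MIN_ACCEPTANCE:
            raise RuntimeError("infeasible ascertainment: acceptance rate < 1e-6")
    rate = accepted / drawn
    return tuple(arr[:n_needed] for arr in out), rate


def sample_trio(
    pools: FounderPools,
    design: StudyDesign,
    dm: DiseaseModel,
    rng: np.random.Generator,
):
    """One ascertained trio: (father, mother, child) score vectors + subpop."""
    (fat, mot, chi, sub), _ = _rejection_sample(
        lambda size, r: _sample_trios_batch(pools, dm, design.trio_mixture, size, r),
        accept_col=4,
        n_needed=1,
        rng=rng,
    )
    return fat[0], mot[0], chi[0], int(sub[0])


def _sample_controls_batch(pools, dm, design, size, rng):
    sub = _draw_subpops(design.control_mixture, size, rng)
    L = pools.n_sites
    G = np.empty((size, L))
    for s in range(2):
        idx = np.flatnonzero(sub == s)
        if idx.size == 0:
            continue
        pool = pools.haplotypes[s]
        hap_idx = rng.integers(0, pool.shape[0], size=(idx.size, 2))
        G[idx] = pool[hap_idx[:, 0]] + pool[hap_idx[:, 1]]
    if design.controls == "random":
        accept = np.ones(size, dtype=bool)
    else:
        accept = rng.random(size) >= disease_probability(G, sub, dm)
    return G, sub, accept


def sample_control(
    pools: FounderPools,
    design: StudyDesign,
    dm: DiseaseModel,
    rng: np.random.Generator,
):
    """One unrelated control genotype-score vector + subpop."""
    (G, sub), _ = _rejection_sample(
        lambda size, r: _sample_controls_batch(pools, dm, design, size, r),
        accept_col=2,
        n_needed=1,
        rng=rng,
    )
    return G[0], int(sub[0])


def sample_population(
    pools: FounderPools,
    dm: DiseaseModel,
    mixture,
    n: int,
    rng: np.random.Generator,
):
    """Unascertained individuals: (G, subpop, affected) — for prevalence checks."""
    G, sub, affected = _sample_trios_batch(pools, dm, mixture, n, rng)[2:]
    return G, sub, affected


def _build_disease_model(
    pools: FounderPools, design: StudyDesign, rng: np.random.Generator
) -> tuple[DiseaseModel, np.ndarray]:
    pooled = pools.pooled_frequency()
    rare = np.flatnonzero((pooled > 0) & (pooled <= design.rare_maf))
    n_causal = int(round(design.causal_fraction * rare.size))
    causal = np.sort(rng.choice(rare, size=n_causal, replace=False))
    beta = np.zeros(pools.n_sites)
    if n_causal:
        maf = pooled[causal]
        if design.paf_exposure == "carrier":
            maf = 2 * maf * (1 - maf) + maf**2
        mag = paf_to_beta(design.paf, maf)
        n_del = int(round(design.deleterious_fraction * n_causal))
        signs = np.full(n_causal, -1.0)
        signs[rng.permutation(n_causal)[:n_del]] = 1.0
        beta[causal] = signs * mag
    return DiseaseModel(beta=beta, causal_indices=causal), pooled


def generate_study(
    design: StudyDesign,
    pm: PopulationModel | None = None,
    seed: int = 0,
) -> tuple[RegionDataset, StudyTruth]:
    """Assemble a full synthetic study: ascertained trios, controls, MAF cap.

    The analysis marker set keeps loci with pooled founder-pool frequency
    <= ``design.max_maf``.  Everything is reproducible from ``seed``.
    """
    pm = pm or PopulationModel()
    rng = np.random.default_rng(seed)
    pools = build_founder_pools(pm, rng)
    dm, pooled = _build_disease_model(pools, design, rng)

    (fat, mot, chi, _sub), trio_rate = _rejection_sample(
        lambda size, r: _sample_trios_batch(pools, dm, design.trio_mixture, size, r),
        accept_col=4,
        n_needed=design.n_trios,
        rng=rng,
    )
    controls = None
    control_rate = 1.0
    if design.n_controls > 0:
        (G, _csub), control_rate = _rejection_sample(
            lambda size, r: _sample_controls_batch(pools, dm, design, size, r),
            accept_col=2,
            n_needed=design.n_controls,
            rng=rng,
        )
        controls = G

    kept = np.flatnonzero(pooled <= design.max_maf)
    if kept.size == 0:
        raise ValueError("no loci pass the analysis MAF cap")
    variants = [
        VariantSite(
            variant_id=f"v{orig + 1}", chrom="1", pos=int(100 * (orig + 1)),
            minor_allele="C", other_allele="A", index=j,
        )
        for j, orig in enumerate(kept)
    ]
    ds = RegionDataset(
        variants=variants,
        trio_ids=[f"trio{i + 1}" for i in range(design.n_trios)],
        father=fat[:, kept],
        mother=mot[:, kept],
        child=chi[:, kept],
        control_ids=(
            [f"ctrl{i + 1}" for i in range(design.n_controls)] if controls is not None else None
        ),
        controls=None if controls is None else controls[:, kept],
        provenance={"source": "conada.simulator", "seed": seed,
                    "filters": [f"pool-maf<={design.max_maf}"]},
    )
    truth = StudyTruth(
        causal_indices=dm.causal_indices,
        beta=dm.beta,
        pooled_maf=pooled,
        kept_indices=kept,
        seed=seed,
        trio_acceptance_rate=trio_rate,
        control_acceptance_rate=control_rate,
    )
    return ds, truth
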