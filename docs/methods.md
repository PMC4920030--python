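# Methods

## The test

`conada` implements a region-level rare-variant association test for
case-parent trios, optionally informed by unrelated population controls.
The test combines three layers:

**Per-variant conditional score.** For variant *l* and trio *i* with
father/mother/child minor-allele scores *f*, *m*, *c* ∈ {0, 1, 2}, the
child's expected score given the parents is e = (f + m)/2 and its
conditional variance is f(2−f)/4 + m(2−m)/4 (0.25 per heterozygous parent).
The region statistic

  T_l = [Σ_i (c_il − e_il)]² / Σ_i Var(c_il | parents)

is asymptotically χ²(1) under the null of no association, and restricted to
heterozygous-parent transmissions reduces algebraically to the classic TDT
(b − c)²/(b + c), where b and c count transmitted and untransmitted minor
alleles. Because inference is conditional on parental genotypes, T_l is
immune to population stratification. Loci with no informative parent keep
their column (T = 0, p = 1) so the locus axis stays aligned with the weight
vector across permutations. The asymptotic tail is used without continuity
correction even at small counts: final inference is permutation-based, so
per-variant P-values only need to be a monotone ordering of evidence.

**Adaptive truncated combination.** The per-variant P-values p_1..p_L are
combined as a weighted truncated Fisher score,
S_j = Σ_l w_l (−ln p_l) I[p_l ≤ θ_j], over a grid of candidate truncation
thresholds (default θ = 0.10, 0.11, …, 0.20; a wider 0.05..0.25 grid of 21
thresholds behaves nearly identically and is available). Truncation removes
neutral variants whose P-values would dilute the signal; because the best
threshold is unknown, every threshold is scored and each column of the
(observed + permuted) score matrix is converted to rank-based P-values.
The row-wise minimum across thresholds (MinP) is referred to its own
permutation distribution — a single-layer Westfall–Young min-P adjustment —
giving one adjusted P-value that already accounts for the threshold search.
Rank P-values count ties inclusively and include the evaluated row in the
denominator, so the adjusted P can never be 0 and the add-one Monte Carlo
convention (1 + count)/(1 + B) holds. All rank quantities are invariant to
rescaling the weights by a positive constant; an equivalent −2 ln p scaling
therefore gives identical results and is not exposed separately.

**Transmission-flip permutation null.** Assuming no recombination within
the region, the pair of non-transmitted parental haplotypes forms a single
alternative diplotype for each child. Each permutation flips every child
independently with probability 1/2 to that unobserved diplotype; the
flipped score at locus l is f_l + m_l − c_l, applied jointly to all loci of
the trio. Parents and controls are untouched, so weights and conditional
expectations are constant across permutations and only the per-trio
deviation rows change sign — which is what makes batched permutation a
single matrix product. For n trios the null support is exactly 2^n flip
patterns; `enumerate_null` walks all of them for n ≤ 20 and serves as the
exact oracle for the Monte Carlo machinery.

## Weights

* **MAF mode** (trios only): w_l = Beta(MAF_l; 1, 25) = 25 (1 − MAF_l)^24,
  with MAF_l computed from trio parents. This is the standard rare-variant
  up-weighting used across SKAT-family region tests.
* **PC mode** (trios + controls): w_l is the Cochran–Armitage trend
  chi-square comparing trio parents against controls on the 2×3 genotype
  table with scores (0, 1, 2); loci whose genotype distributions differ
  between parents and controls are up-weighted. The magnitude convention
  (chi-square vs its square root) is a free choice; the chi-square is the
  default and `statistic="z"` gives the root. Note that weights affect
  power, never validity: mismatched control ancestry can make PC weights
  large at ancestry-informative loci, but the conditional statistic keeps
  the test calibrated (this is checked empirically in the test suite).

A locus with zero weight drops out of every score identically, which is
equivalent to excluding it.

## Sequential Monte Carlo stopping

Permutations accumulate in batches (default 100). From B_min (default 100)
onward, at each batch checkpoint the rank P-values and MinP are recomputed
against the full current pool and the exceedance count
#{b : MinP^(b) ≤ MinP_obs} is evaluated. Sampling stops once the count
reaches h = ⌈1/c²⌉ (16 at the default c = 0.25, targeting a relative
standard error of about 25% for the adjusted P) or at B_max (default
10,000). On an early stop the Besag–Clifford estimate h/B* is reported,
where B* is the draw-order position of the h-th exceedance evaluated
against the full current pool; this keeps the estimator unbiased under the
negative-binomial stopping rule and gives the correct degenerate value 1
when every permutation ties the observed score (e.g. all weights zero).
At exhaustion the add-one estimate (1 + count)/(1 + B_max) is used. The
interaction between rank-based MinP and sequential stopping is inherently a
design choice — recomputing ranks at checkpoints makes the rule
well-defined and cheap, and the checkpointed estimator is validated against
exact enumeration in the tests.

A practical note on Monte Carlo error: because the per-threshold null
distributions are estimated from the same permutation pool, the adjusted-P
estimator's sampling error exceeds the naive binomial SE of the exceedance
count (empirically ~4× at n = 8 trios). The oracle-agreement tests
therefore measure the estimator's spread directly across seeds.

## Synthetic studies

The simulator emulates a stratified exome-region study with two
subpopulations: "EUR-like" (prevalence 0.05) and the more diverse
"AFR-like" (prevalence 0.01). Defaults follow the reference design: 500
trios plus 500 controls, regions of 87 sites, causal variants drawn from
sites with pooled MAF ≤ 0.01 (25% or 75% of them causal), per-locus PAF
0.01 when all causal variants are deleterious or 0.02 when half are
protective, and an analysis marker set capped at pooled MAF ≤ 0.05.

* **Founder pools instead of coalescent sequence.** Site frequencies
  differentiate between subpopulations by a Balding–Nichols draw
  (Beta(p(1−F)/F, (1−p)(1−F)/F) around a shared ancestral frequency p)
  with F_st = 0.10 by default, a typical European–African value. Each
  subpopulation is a finite pool (default 2,000) of binary haplotypes with
  independent sites; resampling individuals from the finite pool induces
  within-region LD. This founder-pool construction is a deliberate,
  documented stand-in for coalescent simulation with real LD maps: it
  reproduces the statistical structure the test depends on (stratified
  frequencies, rare spectrum, pool-induced LD) but not human LD patterns,
  so simulation results say nothing about LD-specific behaviour on real
  data. The ancestral rare spectrum is Beta(0.15, 2) truncated to
  (0, 0.05], putting most sites below 1%.
* **Effect sizes from PAF.** Inverting PAF = f(RR − 1)/[1 + f(RR − 1)] with
  exposure frequency f = MAF gives β = ln(1 + η/((1 − η)·MAF)); rarer causal
  variants get larger effects. A `paf_exposure="carrier"` switch uses the
  carrier frequency 2·MAF(1 − MAF) + MAF² instead, bracketing the
  plausible readings of the PAF calibration.
* **Ascertainment.** Disease risk is logistic:
  P(affected | G) = expit(logit(K_subpop) + β·G). Trios are rejection-
  sampled on an affected child; controls are ascertained unaffected by
  default (`controls="random"` draws them unconditionally — at prevalences
  of 1–5% the difference is minor). The intercept logit(K) sets the
  prevalence exactly only in the absence of genetic effects; with causal
  loci the realized prevalence drifts slightly upward, which the generator
  reports (acceptance rates in the truth metadata) rather than corrects.

## Numerical and policy choices

* Scores count the allele minor among founders (parents + controls pooled);
  ties at 0.5 keep the source file's coding. Frequencies above 0.5 can
  still arise in subsets; weights use the frequency as computed so they
  stay consistent with the statistic's coding.
* Missing data: a trio-locus with any missing member contributes nothing to
  that locus and stays missing under permutation; controls missing at a
  locus drop out of that locus's contingency table. Mendelian
  inconsistencies are a hard error by default (`mendelian_policy=
  "set-missing"` masks the trio-locus instead) because the flip formula
  presumes compatibility.
* P-values of exactly 0 are clamped to the smallest positive float before
  taking logs (practically unreachable through the χ² tail).
* Multi-allelic VCF records are rejected unless `split_multiallelic=True`,
  which decomposes them into one biallelic record per alternate allele.
* Regions are 1-based inclusive, matching VCF convention.

## Problem sizes used in validation

The bundled experiments run at desk scale, chosen so that the full
validation suite completes in minutes: type-I-error calibration uses 1,000
null studies of 100 trios + 100 controls over ~30 rare variants with
B_min = 10 / B_max = 1,000 (a reduced-permutation setting that preserves
validity at the 0.05 and 0.01 levels); the stratification-robustness check
uses 500 such studies with trio mixture 80:20 vs control mixture 20:80; the
power contrast uses 300 replicates of 200-trio studies with 75% of rare
variants causal at PAF 0.01. Exact-enumeration cross-checks run at n = 8
trios against B = 2,000 Monte Carlo permutations.

## Known limitations

* Only trios plus unrelated controls are supported — no general pedigrees,
  no covariates, no X chromosome, no imputation or phasing (the method
  never needs phase).
* Per-variant P-values are asymptotic, not exact binomial; their role is
  ordinal within the permutation scheme.
* The simulator's LD is pool-induced and exchangeable across sites; it does
  not reproduce human haplotype block structure, recombination, or
  admixture gradients within individuals.
* Singleton variants carry essentially no per-variant evidence and are
  truncated away by construction; the method cannot detect causal
  singletons.
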