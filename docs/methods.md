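# Methods

This note documents the statistical model behind `ivmr`, the estimators and
diagnostics it implements, the synthetic-data generator used for validation,
and the numerical and design choices that shape the results.

## Model and assumptions

Two-sample Mendelian randomization estimates the causal effect θ of an
exposure on an outcome from GWAS summary statistics measured in two
non-overlapping samples. For each candidate instrument SNP *j* we observe the
estimated SNP–exposure association β̂ₓⱼ with standard error σₓⱼ and the
SNP–outcome association β̂ᵧⱼ with standard error σᵧⱼ. The working model is

  β̂ᵧⱼ = θ βₓⱼ + αⱼ + εⱼ,  εⱼ ~ N(0, σᵧⱼ²),

where αⱼ is a direct (pleiotropic) effect of the SNP on the outcome. The
core instrumental-variable assumptions are: (i) relevance — the SNP is
robustly associated with the exposure; (ii) independence — the SNP is not
associated with confounders of the exposure–outcome relation; (iii) exclusion
restriction — αⱼ = 0, the SNP affects the outcome only through the exposure.
The estimators below differ in how much they relax (iii). Binary traits are
analysed on the log-odds scale; exponentiated estimates are odds ratios.

## Instrument selection

1. **Significance screen.** Keep SNPs with exposure p < 5×10⁻⁸ (strict
   inequality). The threshold is the conventional genome-wide significance
   level; it operationalizes the relevance assumption.
2. **Clumping.** Greedy selection by ascending p-value (ties broken by
   position, then SNP id). A SNP is dropped when it lies within 10,000 kb of
   an already-selected index SNP on the same chromosome **and** has LD
   r² > 0.001 with it. When positions are unavailable the distance condition
   is treated as satisfied and a warning is issued, making the filter
   conservative. These defaults mirror common practice for obtaining
   approximately independent instruments.
3. **Weak-instrument filter.** Per-SNP F ≈ β̂ₓ²/σₓ²; instruments with F < 10
   are removed. F ≥ 10 is the standard rule of thumb limiting
   weak-instrument bias.
4. **Blocklist.** An optional file of SNP ids known to associate with
   confounders is removed, supporting assumption (ii).

Every input SNP receives exactly one disposition
(`retained`, `dropped_pvalue`, `dropped_clump(rsX)`, `dropped_weak`, …) and
the QC ledger is checked for conservation: counts in = counts out.

## Harmonization

Exposure and outcome records are joined on SNP id and the outcome effect is
expressed relative to the exposure's effect allele:

- identical alleles — keep as is;
- swapped alleles — negate β̂ᵧ and replace the outcome frequency by 1 − eaf;
- strand complements (e.g. A/G vs T/C) — treat as identical (or swapped)
  after complementing;
- palindromic SNPs (A/T or C/G) — strand cannot be resolved from alleles
  alone, so they are **removed by default**. An optional `infer` policy keeps
  palindromic SNPs whose minor-allele frequency is below 0.42 in both studies
  and uses frequency agreement to orient them; 0.42 leaves a margin below 0.5
  where orientation by frequency becomes unreliable.
- anything else (e.g. A/G vs A/C) is incompatible and removed.

## Estimators

All estimators operate on the harmonized instruments.

- **Wald ratio** (per SNP): θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ with first-order standard error
  σᵧⱼ/|β̂ₓⱼ|. The first-order approximation ignores uncertainty in β̂ₓⱼ,
  which is standard and accurate when instruments are strong (F ≥ 10).
- **IVW**: inverse-variance-weighted average of Wald ratios with weights
  wⱼ = (β̂ₓⱼ/σᵧⱼ)², equivalent to weighted regression of β̂ᵧ on β̂ₓ through
  the origin. The fixed-effect standard error is (Σwⱼ)^(−1/2); the
  multiplicative random-effects model (the default) inflates it by
  max(1, √(Q/(k−1))), so heterogeneity widens but never narrows intervals.
  P-values are normal.
- **MR-Egger**: weighted least squares of β̂ᵧ on β̂ₓ with an intercept,
  weights 1/σᵧ², after orienting all β̂ₓ ≥ 0. The slope is a
  pleiotropy-robust estimate under the InSIDE assumption (instrument strength
  independent of direct effects); the intercept estimates the mean
  directional pleiotropic effect, and its test is the Egger intercept test.
  The residual variance scale is floored at 1 and inference uses the t
  distribution with k − 2 degrees of freedom.
- **Weighted median**: the weighted median of the Wald ratios (inverse-
  variance weights), consistent when instruments carrying ≥ 50% of the
  weight are valid. The point estimate interpolates the cumulative weight
  function at 0.5; the standard error comes from a parametric bootstrap
  (default 1,000 draws of β̂ₓ and β̂ᵧ from their sampling distributions) and
  therefore requires an explicit seed.

Minimum instrument counts: 1 (fixed-effect IVW, Wald), 2 (random-effects
IVW), 3 (Egger, weighted median); the pipeline reports a skip rather than an
estimate below these.

## Sensitivity analyses

- **Cochran's Q**: Q = Σ wⱼ(θ̂ⱼ − θ̂_IVW,FE)², referred to χ²ₖ₋₁. Excess
  heterogeneity signals pleiotropy or outliers.
- **Residual-sum outlier test (MR-PRESSO style)**: the observed global
  statistic is the unweighted outcome-scale residual sum of squares, with
  each SNP's expected outcome effect computed from the leave-one-out IVW
  estimate. Its null distribution is simulated (default 1,000 draws) by
  resampling both β̂ₓ and β̂ᵧ from their sampling distributions around the
  leave-one-out fits; the global p-value is (1 + #{RSS* ≥ RSS_obs})/(n_sim+1),
  so it is never exactly zero. Per-SNP outlier p-values are
  Bonferroni-adjusted; when the global test is significant and at least two
  instruments remain after removing flagged outliers, an outlier-corrected
  random-effects IVW estimate is reported along with a distortion test that
  compares the corrected estimate to estimates from random same-size subsets.
  The simulation requires an explicit seed; it runs only with ≥ 4
  instruments.
- **Leave-one-out** random-effects IVW and **funnel data** (ratio vs
  precision 1/se) are provided for plotting and influence diagnostics.

## Direction of causation (Steiger)

For each instrument the variance explained is r²ⱼ = F/(F + n − 2) by default
(requiring only the summary statistics and sample size), or
2·eaf(1−eaf)β̂² when allele frequencies are trusted. Summed r² on the
exposure and outcome sides are compared with a Fisher z test using
√(1/(nₓ−3) + 1/(nᵧ−3)) as the scale. The direction is "correct" when the
instruments explain significantly more variance in the exposure than in the
outcome; a reversed and significant comparison flags potential reverse
causation.

## Synthetic-data generator

`ivmr.simulate` draws complete paired summary-statistic files:

- minor-allele frequencies ~ U(0.05, 0.5); true SNP–exposure effects
  γⱼ ~ N(0.04, 0.012²), a scale at which effects are genome-wide significant
  at biobank sample sizes without being implausibly large;
- standard errors follow the GWAS relation se = 1/√(2·maf(1−maf)·n) with
  default sample sizes nₓ = 337,159 and nᵧ = 216,362, typical of large
  European-ancestry GWAS of a common exposure and a disease outcome;
- outcome effects Γⱼ = θγⱼ + αⱼ, observed effects add independent Gaussian
  noise at the stated standard errors; p-values are exact two-sided normal
  p-values of the written β/se.

Named scenarios fix the generating truth: `null` (θ = 0, k = 80), `causal`
(θ = 0.5, k = 80), `directional_pleiotropy` (θ = 0, αⱼ ~ N(0.01, 0.005²),
k = 80), `outlier` (θ = 0.5, k = 10, one SNP offset by 10 outcome standard
errors), and `reverse` (exposure and outcome roles swapped). Two scenario
parameters deserve explanation:

- The pleiotropy scenario uses θ = 0 because Egger's intercept is attenuated
  toward zero in proportion to θ·E[γ]·σₓ²/var(γ) when the exposure effects
  are measured with error; with θ = 0 the intercept's expectation equals the
  generating mean pleiotropy exactly, making mean-recovery a sharp test of
  the implementation rather than of the (known, model-level) attenuation
  bias.
- The outlier scenario uses k = 10 because a single outlier shifts the IVW
  estimate by roughly (offset/√k) fixed-effect standard errors; at k = 10
  the planted 10-se outlier distorts the pooled estimate strongly enough
  that removing it improves the estimate in the large majority of
  replicates, whereas at k = 80 the shift would drown in replicate noise.

The generator can also plant harmonization hazards: allele swaps
(effect/other alleles exchanged in the outcome file, with β negated and
eaf complemented, so the underlying data are unchanged), strand flips,
palindromic A/T and C/G SNPs (planted consistently in both files), and
duplicate outcome records with inflated standard errors. Truth objects
record θ, per-SNP effects, planted outlier and palindromic ids.

**Scope and limits.** The generator emulates summary statistics only: there
is no individual-level data, no LD between the simulated SNPs (clumping
hazards are exercised with hand-built LD tables in the test suite), no
winner's curse from instrument discovery in the exposure sample, no sample
overlap between the two studies, no binary-trait attenuation of the
log-odds scale, and the per-SNP noise is exactly Gaussian at the nominal
standard errors. It is a test harness for the estimators, not a population-
genetics simulator.

## Reproducibility and numerical choices

- All Monte-Carlo procedures (weighted-median bootstrap, outlier-test
  simulation, synthetic generator) take explicit seeds; the generator splits
  its seed into independent sub-streams for effects, noise and allele
  bookkeeping via `numpy.random.SeedSequence.spawn`, so adding planted
  hazards does not perturb the drawn effect sizes.
- Replicate studies derive per-replicate seeds from a single master seed with
  `SeedSequence.generate_state`, reduced modulo 2³¹ so seeds stay in a
  portable integer range.
- Two-sided p-values are floored at the smallest positive normal double
  rather than reported as 0; p = 1 is reported for a zero statistic with
  zero standard error.
- The 95% confidence multiplier is the conventional 1.959964.
- Egger regression is delegated to `statsmodels` WLS with the covariance
  rescaled by max(1, estimated scale); IVW and the weighted median are
  closed-form and implemented directly, with oracle cross-checks against
  independent references in the test suite.
- Validation replicate counts (1,000 for type-I error, 500 for Q-calibration,
  200 for recovery/pleiotropy/outlier/direction studies, 100 for CI
  coverage) were chosen so that Monte-Carlo standard errors are small
  relative to the property being checked while the full battery runs in
  under a minute.

## Limitations

- First-order Wald standard errors ignore exposure-side uncertainty; with
  the F ≥ 10 filter the omitted term is below a few percent of the variance.
- The multiplicative random-effects model treats heterogeneity as
  proportional to the nominal variances; an additive random-effects model is
  not implemented.
- The outlier test's corrected estimate inherits the usual caveat that
  outlier removal is post-hoc; the distortion p-value quantifies, but does
  not remove, that selection effect.
- Palindromic-SNP frequency inference is unreliable for MAF near 0.5; the
  default policy is removal, at the cost of discarding information.
- The Steiger test assumes the summary statistics' sample sizes are accurate
  and the two samples are independent; sample overlap biases it toward the
  larger study.
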