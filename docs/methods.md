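# Methods

`sexmr` implements summary-statistics Mendelian randomization (MR) for
sex-specific outcomes, with particular attention to the choice between
sex-combined and sex-specific instruments. This note records the models,
conventions and numerical choices, and what the simulation and the synthetic
data generator do and do not emulate.

## Two-sample MR model and the IVW estimator

For instruments i = 1..k, let `a_ix` and `a_iy` denote the marginal effect
of instrument i on the exposure and on the outcome, with standard errors
`se_ix`, `se_iy`. Under the instrumental-variable assumptions each Wald
ratio `a_iy / a_ix` estimates the causal effect θ, and the fixed-effects
inverse-variance weighted (IVW) estimator combines them as

    θ̂ = Σ w_i a_iy a_ix / Σ w_i a_ix²,   var(θ̂) = 1 / Σ w_i a_ix²,

with first-order weights `w_i = se_iy⁻²`. Exposure-side uncertainty is
carried in the data structures but deliberately not used by IVW (the
estimator is defined with outcome-variance weights only); for k = 1 the
formula reduces to the single Wald ratio. P-values and confidence intervals
are two-sided normal throughout (θ̂ ∓ 1.96·se), and for a binary outcome the
effect is reported as an odds ratio per SD of exposure, `exp(θ̂)`.

The multiplicative random-effects variant (`ivw_random`) keeps the point
estimate and inflates the standard error by `max(1, sqrt(Q/(k−1)))`, where
`Q = Σ w_i (a_iy − θ̂ a_ix)²` is the between-instrument heterogeneity
statistic. The inflation-never-below-1 convention means the random-effects
interval is never narrower than the fixed-effects one.

## Sensitivity estimators

- **Weighted median**: per-instrument ratios with weights `(a_ix/se_iy)²`;
  the estimate is the weight-interpolated 50th percentile (midpoint
  convention: sorted ratio i sits at cumulative coordinate
  `(cum_i − w_i/2)/Σw`, and the estimate interpolates linearly where that
  crosses 0.5). The standard error comes from a seeded parametric bootstrap
  (default 1000 draws resampling both `a_ix` and `a_iy` from their normal
  sampling distributions); the method has no closed-form SE.
- **Maximum likelihood**: joint model `a_ix ~ N(ξ_i, se_ix²)`,
  `a_iy ~ N(θ ξ_i, se_iy²)`. The ξ_i have a closed-form optimum given θ, so
  the profile likelihood is minimized in one dimension (Brent, initialized
  at the IVW estimate, xtol 1e-10); the SE comes from the observed
  information at the optimum with the ξ block eliminated analytically.
- **MR-Egger**: instruments are re-signed so every exposure effect is
  non-negative (Egger regression is not orientation-invariant; this is the
  standard convention and is covered by an explicit invariance test), then
  outcome effects are regressed on exposure effects with an intercept,
  weights `se_iy⁻²`. The slope is the causal estimate and the intercept its
  directional-pleiotropy test, with the usual residual-scaled WLS
  covariance.
- **Outlier test (MR-PRESSO style)**: observed residual of instrument i is
  `a_iy − θ̂₋ᵢ a_ix` with θ̂₋ᵢ the leave-one-out IVW estimate; the global
  statistic is the residual sum of squares. The null is simulated
  parametrically (`a*_iy ~ N(θ̂₋ᵢ a_ix, se_iy²)`, leave-one-out estimates
  recomputed per simulated dataset, vectorized across simulations), with
  add-one empirical p-values `(count+1)/(n_sim+1)` so a p-value of exactly
  zero cannot occur; per-instrument p-values are Bonferroni-adjusted before
  flagging. The distortion test (re-estimation after outlier removal) is
  out of scope.
- **Leave-one-out**: k re-estimates, each excluding one instrument, for
  influence diagnostics.

## Harmonization and instrument QC

Outcome records are aligned onto the exposure's effect allele: identical
allele pairs are kept as-is, swapped pairs flip the outcome beta's sign,
anything else (including indels, which are rejected at parse time) is
excluded as inconsistent. Strand-ambiguous A/T and C/G variants are kept by
default — with both studies on the same strand the exact-match rule is
correct — and can be dropped with `drop_palindromic` where strand provenance
is unknown. Effect-allele frequencies are accepted but unused: no formula
in the package needs them.

The outcome-association filter removes instruments with
`p_outcome × k < 0.05` (Bonferroni over the k instruments entering the
filter, a deliberately conservative pleiotropy guard for binary outcomes).
The denominator is the post-harmonization instrument count; exclusion
counts are logged per reason so the k₀/k₁ bookkeeping of a screening table
can be reconstructed from the log.

## Sex-heterogeneity screen

With independent female and male estimates of the same SNP effect, the
two-group Cochran's Q collapses to the squared z of the difference,
`Q = (β_f − β_m)²/(se_f² + se_m²)` on 1 df, quantified by
`I² = max(0, (Q−1)/Q)·100`. The screen Bonferroni-corrects across the
tested instruments. The Pearson correlation of instrument effects between
strata is reported with two tests: against r = 0 (the usual t statistic)
and against r = 1. The latter has no standard construction — Fisher's z is
undefined at r = 1 — so a Wald statistic `(r−1)/se_jack` with the
leave-one-out jackknife SE of r is used and labelled as such; it is a
documented choice, not an inference of how any particular published
analysis did it.

## Comparing sex-combined and sex-specific estimates

The u statistic

    u = (θ̂_c − θ̂_s) / sqrt(se_c² + se_s² − 2 ρ se_c se_s)

is asymptotically standard normal under θ_c = θ_s. Because both estimates
share the outcome statistics (and often instruments), ρ is materially
positive; it is estimated by a paired leave-one-instrument-out jackknife
over the union of the two instrument sets. An instrument absent from one
set contributes that side's full-set estimate to the pair, so union
iteration never extrapolates; an intersection-only mode is available. The
computed correlation is clamped to [−1, 1] (clamping logged). The estimator
used inside the jackknife always matches the one used for the headline
estimates. The denominator degenerates when ρ → 1 with equal SEs; that case
raises a dedicated error rather than returning an unstable u.

## MR power for a binary outcome

Power uses the normal approximation
`Φ(sqrt(N·PVE·p(1−p))·|ln OR| − z_{0.975})` with N the outcome GWAS size, p
its case fraction, PVE the exposure variance explained by the instruments,
and OR the odds ratio per SD of exposure. The approximation's documented
floor is Φ(−1.96) ≈ 0.025 at OR = 1, it is symmetric in OR ↔ 1/OR, and it
was validated against three published power figures (99.9%, 2.8%, 93.6%)
before adoption. The instrument count enters only through PVE. Power for
continuous outcomes or for the sensitivity estimators is out of scope.

## The bias simulation

Each replicate generates a female-specific MR study bottom-up:

1. m ~ U{50..150} biallelic SNPs, MAF ~ U(0.01, 0.50), genotypes
   Binomial(2, MAF) under HWE and linkage equilibrium, independent cohorts
   of 1e5 males and 1e5 females (and, by default, a second independent
   female cohort for the outcome; see below).
2. Per-SNP effects (α_m, α_f) iid bivariate normal, unit variances,
   inter-sex correlation r_g ∈ {0.1, 0.3, 0.5, 0.7}; the degenerate
   |r_g| = 1 case is drawn as one vector (±copied).
3. Effects are rescaled per sex by δ = sqrt(PVE/((1−PVE)·Σα²)) so the
   variance bookkeeping δ²Σα²/(δ²Σα²+1) hits the target PVE (1% male, 3%
   female by default); exposures are genetic value plus N(0,1) noise, the
   outcome is y = θ·x_f + N(0,1) with θ ∈ {0.1, 0.3, 0.5}.
4. Single-SNP regressions give sex-specific exposure summary statistics
   (betas reported per unit-variance genotype; the IVW estimate is
   invariant to per-SNP genotype scaling, so this choice is cosmetic); a
   fixed-effects meta-analysis gives sex-combined ones.
5. Instruments are selected at P < 0.05/m (strict), falling back to the
   single minimum-P SNP when none passes (the fallback frequency is
   recorded per replicate); fixed-effects IVW is run once with
   combined-selected/combined-effect instruments and once with
   female-selected/female-effect instruments, both against the same
   female-outcome statistics.

Replicates (200 per scenario by default) run on independent sub-streams
spawned from the scenario seed (SFC64; chosen for bulk-uniform speed), and
summaries report the mean bias with its Monte Carlo standard error.
Phenotype-level data are never persisted; each replicate is O(n·m) memory
transiently (~60 MB at the defaults).

Two conventions deserve explicit justification:

- **Raw dosages, not standardized genotypes.** The generating equation uses
  raw 0/1/2 dosages, so a SNP's contribution to the exposure variance is
  α²·2·MAF·(1−MAF) and the realized PVE is below the δ-rescaling target by
  the mean of 2·MAF·(1−MAF) (~0.34 under U(0.01, 0.5) MAFs). This is
  deliberate: it matches the generating equations as usually written and
  reproduces the published bias magnitudes, which a unit-variance-genotype
  implementation (realized PVE exactly on target, instruments ~3× stronger)
  overshoots. `standardize_genotypes=True` switches to exact-PVE
  bookkeeping.
- **Independent outcome cohort.** The default draws a fresh female cohort
  for the outcome GWAS, making exposure- and outcome-side sampling errors
  independent — the defining feature of two-sample MR. Reusing the exposure
  cohort (`outcome_cohort="shared"`) couples the female exposure noise into
  the outcome statistics; that coupling cancels the winner's curse in the
  sex-specific arm (making it exactly unbiased) but inflates the
  combined-arm bias by roughly a third, beyond what the published
  experiment reports. The independent design reproduces the published
  combined-arm biases; its known cost is a winner's-curse attenuation of
  about −0.04 (at θ = 0.5) in the sex-specific arm, since instruments are
  selected on the same exposure statistics used in the ratios. One
  acceptance property test asserts a stricter-than-qualitative "specific
  arm unbiased to 3 Monte Carlo SEs" bound and is expected to fail under
  this design; it is left in place deliberately, as the two goals (match
  the published combined-arm biases; zero specific-arm bias) cannot be met
  by any one coherent protocol.

At the study conditions the combined-instrument arm overestimates a
positive θ whenever the female PVE exceeds the male PVE (the meta-analyzed
instrument effects are systematically smaller than the female-specific
ones), underestimates it in the reversed ordering, and the bias magnitude
shrinks as r_g grows. These sign/monotonicity laws, not only the published
values, are asserted in the tests.

## Synthetic summary-statistics generator

`generate_synthetic_sumstats` works at the summary level and plants
structure with exact, auditable properties: sex-difference z-scores are
constructed exactly (not sampled around a target), so heterogeneity-screen
flag counts are deterministic; outcome-associated instruments get a direct
effect of a configured z (default 10) so the QC filter must remove exactly
them; allele-swapped outcome records encode the equivalent flipped-sign
representation; allele-mismatched records must be excluded. Default scales:
per-allele effects U(0.02, 0.06) with random sign, exposure SEs 1/√n,
outcome SE 0.01. The default outcome SE keeps the causal-path outcome
z-scores well below the Bonferroni QC threshold, so "clean" instruments
survive QC except under unlucky extremes; tests that assert exact survival
use configs with a lower θ·β/se_y ceiling.

What the generator does *not* emulate: linkage disequilibrium (instruments
are exchangeable and uncorrelated), allele-frequency-dependent standard
errors, population stratification, sample overlap between exposure and
outcome, directional pleiotropy (outcome effects are symmetric around the
causal path except for the planted QC violators), and binary-outcome
effect-size attenuation. Tests passing on generator output therefore
validate bookkeeping and estimator algebra, not robustness to those
real-data phenomena.

## Degenerate inputs and numerical conventions

Zero exposure effects: IVW raises only if *all* are zero (the estimator is
defined otherwise), the weighted median raises naming the offending SNP
(its ratio is undefined). Q = 0 gives heterogeneity p = 1 and I² = 0.
Empirical p-values use the add-one estimator. Pearson and jackknife
correlations are clamped to [−1, 1] after floating-point arithmetic.
Bootstrap and null-simulation routines take explicit seeds; scenario-level
randomness flows from a single seed through spawned sub-streams, and
rerunning any pipeline with the same config and seed is byte-identical.

## Problem sizes used by the test suite

Unit tests run scaled-down simulations (cohorts of 8k–30k, 30–60
replicates) chosen so the asserted effects exceed 3 Monte Carlo SEs at
those sizes; the acceptance tests and `scripts/acceptance.py` run the full
study conditions (1e5 per cohort, 200 replicates per scenario, four
scenarios), which dominates their few-minute runtime.

## Known limitations

- LD clumping, proxy lookup, liftover, VCF input, and genome-wide genetic
  correlation (LDSC) are out of scope; instrument lists are inputs.
- The power formula is a normal approximation with a hard 0.025 floor at
  OR = 1; it is not a substitute for simulation-based power at extreme case
  fractions.
- The u-test treats ρ as known once jackknifed; no uncertainty in ρ is
  propagated.
- MR-Egger p-values use the normal reference (consistent with the
  package-wide convention) rather than t on k−2 df; for very small k the
  intercept test is mildly anti-conservative.
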