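# Methods

## Model

`bivpois` analyses two correlated non-negative counts per woman — years of
schooling (y₁) and children ever born (y₂) — with a parallel
(non-exchangeable) bivariate Poisson regression. The joint distribution is
the trivariate-reduction bivariate Poisson: (Y₁, Y₂) = (A + C, B + C) with
independent A ~ Poisson(θ₁), B ~ Poisson(θ₂), C ~ Poisson(θ₃), whose pmf is

    f(y₁, y₂) = e^{−θ₁−θ₂−θ₃} (θ₁^{y₁}/y₁!)(θ₂^{y₂}/y₂!)
                Σ_{k=0}^{min(y₁,y₂)} k! (θ₃/(θ₁θ₂))^k C(y₁,k) C(y₂,k),

so cov(Y₁, Y₂) = θ₃ ≥ 0. Each margin gets its own log-link linear predictor
over a shared design matrix, log θ_ij = xᵢᵀβ_j, with reference-coded
categorical covariates. The dependence rate θ₃ is a nuisance parameter:
although the pmf is formally written with θ₃ ∈ ℝ, the expression is a valid
probability mass function only for θ₃ ≥ 0, and the package enforces that
restriction.

Note a parametrisation subtlety: under trivariate reduction E(Y_j) = θ_j + θ₃,
so θ_j equals the marginal mean only at θ₃ = 0. The package treats θ₁, θ₂ as
the link-modelled rates throughout.

## Estimation

Coefficients are estimated by maximising the joint log-likelihood with θ₃
fixed at 0, which factorises into two independent log-link Poisson
likelihoods. Each margin is maximised by Newton iterations with step-halving,
initialised at β = (log(ȳ + 0.1), 0, …, 0); convergence requires the maximum
score component divided by the sample size to fall below `tol` (default
1e-8), with a cap of `max_iter` (default 100) iterations. Standard errors
come from the inverse observed information Xᵀdiag(θ̂)X per margin, and
p-values are two-sided Wald normal tests. AIC is −2ℓ + 2p with p counting all
estimated regression coefficients. All factorial terms use log-gamma, and the
k-sum in the pmf/likelihood is evaluated by log-sum-exp, so large counts do
not overflow.

An optional mode (`estimate_theta3=True`) then profiles a constant θ₃ ≥ 0 on
a grid (with a bounded scalar refinement) holding β̂ fixed, adding one counted
parameter. Because the marginal fits already absorb the common-shock mean
into exp(x'β̂), this two-stage profile *attenuates* θ̂₃ well below a generative
shock rate (simulations with true θ₃ = 1 profile to ≈ 0.1). That is inherent
to estimating the marginals first; the profile should be read as a
dependence *detector* (θ̂₃ > 0 plus a likelihood gain), not an unbiased
estimator of the shock rate. The reported outcome dependence is instead
post-estimated, as described next.

## Correlation post-estimation

The schooling–fertility association is reported as the Spearman rank
correlation of the fitted marginal means θ̂_i1, θ̂_i2 (basis `"fitted"`), with
the Spearman correlation of the observed counts (basis `"raw"`) alongside.
Without ties the classical formula ρ = 1 − 6Σd_i²/(n(n²−1)) is exact; raw
counts always carry heavy ties, so the implementation uses the standard tie
correction — the product-moment correlation of average ranks — which reduces
to the classical formula in the tie-free case (tested to 1e-12). The default
p-value uses the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of
freedom; a seeded permutation p-value is available
(`p_method="permutation"`, default 10,000 permutations).

## Outlier diagnostics

Each margin's deviance residual is

    d_ij = sgn(y_ij − θ̂_ij) · √(2[y_ij log((y_ij + δ)/θ̂_ij) − (y_ij − θ̂_ij)]),

with smoothing constant δ = 1e-6 keeping the logarithm finite at zero
counts; for y = 0 the y·log term is exactly zero, giving d = −√(2θ̂). The
overall statistic is the average d*_i = (d_i1 + d_i2)/2, thresholded at
±1.96 and ±2.58 (both configurable). Records with d* < −cutoff are
"over-predicted" (observed below prediction), d* > +cutoff "under-predicted".

Two calibration caveats are deliberate and documented rather than corrected:

- d* averages two roughly unit-variance residuals, so its variance is at
  most one and the normal cutoffs are conservative (well-specified data
  flag ≲ 1% at 1.96, not 5%).
- Poisson deviance residuals have a negative mean that grows as the rate
  shrinks (≈ −0.27 at mean 0.2, −0.11 at mean 3, −0.05 at mean 12), so
  mean(d*) sits slightly below zero even under a correct model; it is
  within ±0.1 when fitted means stay mid-range (roughly 3–14), the
  operating region of the shipped calibration scenario.

The remove-and-refit pipeline flags at every cutoff against the *single*
full-data fit, then independently drops each cutoff's flags and refits from
scratch (single pass, no iterative re-flagging), reporting reduced-fit
coefficients, AIC, fitted-mean and raw correlations, and per-term coefficient
deltas with sign- and significance-change flags (α = 0.05). A cutoff that
would flag more than half the sample is aborted with a diagnostic instead of
refitted.

## Synthetic data generator

The generator emulates DHS-style woman records: eight categorical covariates
drawn from configurable frequency tables, and two continuous covariates —
current age, uniform integer on 15–49, and age at first sex, uniform integer
on 12–22 resampled so it never exceeds current age. Outcomes come from the
trivariate reduction above, so the generated joint law is exactly the model's
pmf. The common shock (θ₃ ≥ 0) can only induce non-negative dependence; the
negative schooling–fertility association is produced by shared covariates
entering the two margins with opposite signs — the same mechanism by which
the fitted-mean correlation of the regression becomes strongly negative.

Shipped scenarios (all seeded, bit-reproducible):

- **default_scenario** — category frequencies follow the overall-sample
  distribution of the 2004 Malawi DHS (exact count ratios); coefficients
  chosen once to give marginal means ≈ 5.2 schooling years and ≈ 2.6
  children and a fitted-mean Spearman ρ ≈ −0.6, with the raw-count ρ
  ≈ −0.28 — roughly half the model-based magnitude, as observed in such
  surveys. Continuous ages enter with opposite signs (age −0.014/+0.055;
  age at first sex +0.048/−0.045 per year on the log scale).
- **recovery_scenario** — five single-column covariates (three binary
  indicators, two continuous ages; six coefficients per margin) for
  parameter-recovery studies at n = 5,000.
- **calibration_scenario** — coefficients keep both margins' fitted means
  in ≈ 3–14, the region where the residual-bias caveat above leaves
  mean(d*) within ±0.1.
- **contamination_scenario** — a stress design for outlier recovery; see
  below.

Contamination (`swap_extremes`) overwrites a seeded fraction of records
against their covariate prediction: records with predicted schooling above
the sample median get (0 schooling, 5+ children), records below get (9+
schooling, 0 children), with the excess above the floors drawn from Poisson
spreads (`contaminated_parity_extra`, `contaminated_schooling_extra`). This
mirrors the extreme-cell outcome profile such models flag in real surveys.
It is off by default.

### Why the contamination scenario uses aligned signals

When fitted means are strongly negatively correlated, an extreme swap
produces *opposite-signed* marginal residuals — e.g. predicted (12 schooling,
1.5 children) observed as (0, 5) gives d₁ ≈ −4.9 but d₂ ≈ +2.2 — which
largely cancel in d* and leave recall near 0.1. The contamination scenario
therefore uses a dominant wealth effect that makes predicted schooling
bimodal (≈ 2 vs ≈ 12) with the fertility signal *positively* aligned, so
each cluster's predicted parity sits near the opposite swap's floor: a
swapped record then contradicts both margins simultaneously and |d*| clears
1.96. At 1% contamination, n = 10,000, recall at the 1.96 cutoff is ≈ 0.85
(minimum 0.80 over 50 seeds) and removing the flags brings the refitted
coefficients closer to truth in ≈ 98% of replicates. This scenario is a
stress test of the diagnostic, not a demographic calibration.

### What passing tests do and do not show

The generator draws covariates independently per woman (no cluster/strata
structure, no survey weights, no within-household correlation), uses uniform
age distributions rather than survey age pyramids, and generates outcomes
exactly from the fitted model family. Passing tests therefore demonstrate
correctness of the estimator, residuals, and pipeline under the model's own
assumptions — not robustness to model misspecification, informative
sampling, or measurement error in real DHS data.

## Numerical choices and degenerate inputs

- Linear predictors are capped at |x'β| ≤ 30; beyond that the exponentiated
  mean is treated as overflow and the caller is advised to rescale.
- Newton divergence (|β| > 30, a quasi-separation signature) raises rather
  than returning a nonsense fit; non-convergence within `max_iter` returns
  `converged=False`.
- Complete-case analysis: rows missing any required column are dropped and
  counted per fit.
- Constant encoded columns are rejected at fit time (singular information)
  but tolerated when predicting on a subset.
- Chi-square tests are Pearson without continuity correction; a zero
  expected cell raises with advice to merge categories.
- An empty residual set or a constant input to Spearman raises; zero flagged
  records yield an empty outlier profile, not an error.

## Problem sizes used in checks

Simulation-based checks use n = 5,000 records (n = 10,000 for the
contamination study, 50 replicates; 20 seeds for parameter recovery) —
comfortably identifying all coefficients at survey-like effect sizes while
keeping the full suite fast.

## Known limitations

- θ₃ enters estimation only as an optional constant profile; covariate-
  dependent dependence q(x) is not modelled.
- The deviance-residual cutoffs inherit the conservatism and small-mean bias
  described above; users analysing outcomes with very low rates should
  expect a left-shifted d* distribution.
- No survey-design features (weights, clustering, stratification) anywhere
  in the pipeline.
- Zero-truncated and negative-binomial variants are out of scope.
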