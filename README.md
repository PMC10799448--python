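# bivpois

Bivariate Poisson regression with deviance-residual outlier diagnostics for
paired count outcomes — built for the demographic question of how a woman's
years of schooling and her number of children ever born co-vary, and how
much unusual women distort that association.

## Who this is for

Demographers and biostatisticians analysing two correlated counts per
subject (schooling years and parity in DHS-style surveys being the
motivating case) who want, in one tested workflow:

1. a **parallel bivariate Poisson regression** — each outcome gets its own
   log-link coefficient vector over shared covariates;
2. **outlier detection** through averaged deviance residuals with
   configurable normal cutoffs (±1.96, ±2.58);
3. a **remove-and-refit comparison** quantifying how flagged records move
   the coefficients, the AIC, and the outcome correlation;
4. **Spearman post-estimation** of the outcome dependence from fitted
   marginal means, alongside the raw-count correlation.

A synthetic-data generator with known ground truth (trivariate-reduction
outcomes over DHS-like covariates, optional extreme-value contamination)
makes every stage testable without access-gated survey microdata.

## The model

For woman *i* with covariate vector xᵢ, the counts follow the bivariate
Poisson pmf

    f(y₁, y₂ | θ₁, θ₂, θ₃) = e^{−θ₁−θ₂−θ₃} (θ₁^{y₁}/y₁!)(θ₂^{y₂}/y₂!)
                             Σₖ k! (θ₃/(θ₁θ₂))^k C(y₁,k) C(y₂,k)

with log θᵢ₁ = xᵢᵀβ₁ (schooling), log θᵢ₂ = xᵢᵀβ₂ (fertility), and
dependence rate θ₃ ≥ 0 treated as a nuisance (fixed at 0 during coefficient
estimation; optionally profiled afterwards). Outlyingness of record *i* is
the average of its two marginal deviance residuals,

    d*ᵢ = (dᵢ₁ + dᵢ₂)/2,
    dᵢⱼ = sgn(yᵢⱼ − θ̂ᵢⱼ) √(2[yᵢⱼ log((yᵢⱼ+δ)/θ̂ᵢⱼ) − (yᵢⱼ − θ̂ᵢⱼ)]),  δ = 10⁻⁶,

and the reported outcome dependence is the Spearman rank correlation of
the fitted means θ̂ᵢ₁, θ̂ᵢ₂. See `docs/methods.md` for assumptions,
numerical choices and known limitations.

## Worked example

```python
from bivpois import (
    DiagnosticsConfig, correlation_fitted, correlation_raw,
    default_scenario, fit, run_pipeline, simulate,
)

cfg = default_scenario(n_records=5000, seed=1)   # DHS-like ground truth
records = simulate(cfg)
spec = cfg.model_spec()

result = fit(records, spec)
print(result.loglik, result.aic)                 # -19325.6  38719.2
print(result.coefficient_table().head(3))

report = run_pipeline(records, spec, DiagnosticsConfig())
print(report.correlation_fitted_full["rho"])     # -0.6314
print(report.correlation_raw_full["rho"])        # -0.3038
for entry in report.cutoffs:
    print(entry["cutoff"],
          entry["outlier_report"]["n_flagged"],
          entry["correlation_fitted_reduced"]["rho"])
# 1.96  30  -0.6305
# 2.58   1  -0.6312
```

Reading the numbers: the fitted-mean Spearman correlation (−0.63) is
strongly negative and roughly double the raw-count correlation (−0.30),
because ranking the *fitted* means strips the Poisson noise that dilutes
the raw ranks. At the 1.96 cutoff, 30 of 5,000 records (0.6%) are flagged —
mostly over-predicted, i.e. women with fewer schooling years and children
than their covariates predict — and refitting without them shifts the
correlation only slightly (−0.6305), while the coefficient deltas in
`entry["coefficient_deltas"]` show which effects moved.

The same workflow is scriptable from a shell:

```sh
bivpois simulate --out records.csv --seed 1 --n-records 5000
bivpois pipeline --input records.csv --spec spec.yaml --out-prefix run
```

which writes `run_report.json` plus residual/coefficient/delta CSVs.

There is also a scikit-learn-style estimator wrapping the same fit:

```python
from bivpois import BivariatePoissonRegression
est = BivariatePoissonRegression(spec=spec).fit(
    records[[c.name for c in spec.covariates]],
    records[[spec.outcome1, spec.outcome2]],
)
est.predict(records.head(3)[[c.name for c in spec.covariates]])  # (3, 2) means
```

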