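# mrforge

Two-sample and multivariable Mendelian randomization (MR) from GWAS
summary statistics, with a seeded synthetic summary-statistics generator
so the whole pipeline can be validated against a known generative truth.

MR treats genetic variants as instrumental variables for an exposure: if
variant *j* shifts the exposure by γ̂ⱼ (SE σxⱼ) and the outcome by Γ̂ⱼ
(SE σyⱼ) in two independent GWAS, and the instrument assumptions hold,
each Wald ratio βⱼ = Γ̂ⱼ/γ̂ⱼ estimates the causal effect θ. The package is
aimed at epidemiologists and statistical geneticists who run this design
from Python: it covers instrument selection, allele harmonization, the
standard estimator battery, the standard sensitivity analyses, and
multivariable adjustment for measured confounders, all with explicit
audit trails.

## What it computes

**Univariable estimators** (module `mrforge.estimators`):

- fixed-effect IVW, the primary estimator:
  θ̂ = Σⱼ wⱼβⱼ / Σⱼ wⱼ with wⱼ = γ̂ⱼ²/σyⱼ² — identical to weighted least
  squares of Γ̂ on γ̂ through the origin; a multiplicative random-effects
  variant inflates the SE by max(1, √(Q/(J−1)))
- MR-Egger: Γ̂ⱼ = β₀ + β₁γ̂ⱼ weighted by 1/σyⱼ² after orienting γ̂ⱼ ≥ 0;
  the slope is robust to directional pleiotropy under InSIDE and the
  intercept β₀ tests for it
- weighted and simple median (interpolated weighted quantile of the
  ratios), consistent when ≥ 50% of the weight is valid
- simple and weighted mode (kernel-smoothed ratio density argmax), with
  parametric-bootstrap SEs
- odds-ratio scale reporting (`exp(β)` with CI) for binary outcomes

**Sensitivity** (`mrforge.sensitivity`): Cochran's Q heterogeneity test,
Egger intercept test, leave-one-out IVW, MR-PRESSO (global RSS test,
per-SNP outlier flags with Bonferroni correction, distortion test), and
funnel-plot data.

**Multivariable MR** (`mrforge.mvmr`): IVW, Egger, median (weighted L1),
LASSO (per-SNP pleiotropy intercepts with a heterogeneity stopping rule)
and Huber-robust regression of Γ̂ on several exposures' effect columns
jointly, estimating direct effects. Exact collinearity (e.g. pulse
pressure alongside systolic and diastolic blood pressure) raises a rank
error naming the offending columns.

**Instrument selection** (`mrforge.instruments`): p < 5×10⁻⁸ filter,
greedy LD clumping at r² > 0.001, per-SNP F statistics (F > 10), variance
explained, and a confounder-trait screen against a local association
catalog (p < 10⁻⁵, LD proxies at R² ≥ 0.8).

**Pipeline and scenario** (`mrforge.pipeline`, `mrforge.scenario`):
configured univariable runs with full SNP ledgers, confounder screening
and classification, adjusted MVMR passes, a positive-control check, and
Bonferroni-corrected reporting.

**Synthetic data** (`mrforge.simulate`): standardized-trait GWAS pairs
with closed-form SEs (σ = 1/√(2·n·maf(1−maf)), case-fraction inflation
for binary outcomes), configurable causal effect, balanced or directional
pleiotropy with optional InSIDE violation, block LD and planted
confounder catalogs — all reproducible from one seed.

## Worked example

```sh
python examples/univariable_mr.py
```

simulates a 50-instrument study with true θ = 0.2, keeps the 31
genome-wide-significant instruments, and prints:

```
method                 beta      se              95% CI          p
ivw_fixed            0.1901  0.0136    [ 0.164,  0.217]   1.84e-44
egger_slope          0.2463  0.0369    [ 0.174,  0.319]   2.58e-07
egger_intercept     -0.0042  0.0026    [-0.009,  0.001]   1.07e-01
weighted_median      0.2101  0.0211    [ 0.169,  0.251]   2.49e-23
simple_mode          0.2020  0.0396    [ 0.124,  0.280]   3.39e-07
weighted_mode        0.2201  0.0255    [ 0.170,  0.270]   5.99e-18

Cochran Q = 38.7 on 30 df (p = 0.134); PRESSO global p = 0.154, 0 outliers flagged
```

Every estimator's CI covers the true effect, and — since no pleiotropy
was simulated — the Egger intercept is near zero and neither Q nor
MR-PRESSO fires. The other scripts in `examples/` walk instrument
selection, multivariable MR with a deliberately collinear exposure, and
the full packaged study scenario.

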