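# Methods

This note records the statistical models implemented in mrforge, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## The two-sample MR model

For instrument *j* the observed quantities are the SNP-exposure
association γ̂ⱼ with standard error σxⱼ and the SNP-outcome association
Γ̂ⱼ with standard error σyⱼ, estimated in two non-overlapping GWAS and
harmonized to a common effect allele. Under the instrumental-variable
assumptions (association with the exposure; independence from
confounders; no effect on the outcome except through the exposure) each
Wald ratio βⱼ = Γ̂ⱼ/γ̂ⱼ estimates the causal effect θ; for a binary
outcome analysed on the log-odds scale, exp(θ) is an odds ratio.

### Univariable estimators

**IVW.** θ̂ = Σwⱼβⱼ/Σwⱼ with first-order weights wⱼ = γ̂ⱼ²/σyⱼ² — the
inverse variance of βⱼ when only outcome-side noise is counted. This is
algebraically the weighted least-squares slope of Γ̂ on γ̂ through the
origin with weights 1/σyⱼ², which is how the unit tests cross-check it
against an independent regression oracle. The fixed-effect SE is
(Σwⱼ)^(−1/2); the multiplicative random-effects variant scales it by
max(1, √(Q/(J−1))). The fixed-effect form is the primary estimator;
p-values are two-sided normal, intervals use z = 1.959964 exactly.

**Wald ratio SEs.** First-order σyⱼ/|γ̂ⱼ| is the default, consistent with
the IVW weighting; the second-order form
√(σyⱼ²/γ̂ⱼ² + Γ̂ⱼ²σxⱼ²/γ̂ⱼ⁴) is available by flag.

**MR-Egger.** Each SNP is oriented so γ̂ⱼ ≥ 0, then Γ̂ is regressed on γ̂
with a free intercept, weights 1/σyⱼ². The intercept estimates the mean
directional pleiotropic effect (valid under InSIDE: pleiotropy
independent of instrument strength); the slope remains a consistent
causal estimate. SEs carry a multiplicative overdispersion factor
bounded below by 1 and tests use a t reference with J−2 df — the least
surprising published convention.

**Weighted median.** Ratios sorted ascending with normalized weights pⱼ;
the estimate interpolates β linearly in the cumulative midpoint
sⱼ = Σ_{k≤j}pₖ − pⱼ/2 at s = 0.5. Equal weights give the ordinary
median. Consistent while valid instruments carry more than half the
weight.

**Mode-based estimate.** Normal-kernel density of the ratios with
bandwidth h = φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5) (φ = 1 default),
evaluated on a grid spanning the ratio range padded by 3h; the estimate
is the grid argmax, weighted or unweighted. The grid has at least 512
points and is refined automatically (up to 8192) whenever stray extreme
ratios stretch the range, so the argmax is never quantization noise —
this matters inside the parametric bootstrap, where resampled γ̂ near
zero can produce enormous ratios. If the bandwidth degenerates (all
ratios identical) the common ratio is returned directly.

**Bootstrap SEs.** Median and mode SEs come from 1,000 (default)
parametric-bootstrap replicates resampling γ̂ⱼ ~ N(γ̂ⱼ, σxⱼ) and
Γ̂ⱼ ~ N(Γ̂ⱼ, σyⱼ), reproducible from a seed; CIs are normal-based for
comparability across estimators.

### Sensitivity diagnostics

**Cochran's Q** uses the same first-order weights as IVW (so Q is
minimized exactly at the IVW estimate), with a χ²(J−1) reference.

**Leave-one-out** refits IVW with each instrument omitted and flags
omissions that push the estimate outside the full-set 95% CI or flip its
sign. It is defined for IVW only.

**MR-PRESSO.** The observed statistic is RSS = Σⱼ(Γ̂ⱼ − θ̂₋ⱼγ̂ⱼ)²/σyⱼ²
with θ̂₋ⱼ the leave-one-out IVW estimate. Its null distribution is
simulated by redrawing γ̂*ⱼ ~ N(γ̂ⱼ, σxⱼ), Γ̂*ⱼ ~ N(θ̂₋ⱼγ̂ⱼ, σyⱼ) and
recomputing the statistic (including the leave-one-out estimates) from
scratch, n_sim = 1,000 times by default. All PRESSO p-values use the
(1 + #exceedances)/(n_sim + 1) convention, so none is exactly zero at
desk-scale simulation counts. Per-SNP outlier p-values compare each
observed weighted squared residual to its simulated distribution and are
Bonferroni-scaled by J; the distortion test compares the
outlier-removal shift of the IVW estimate against shifts from removing
random subsets of the same size (absent when nothing is flagged; an
explicit status marks the all-flagged case).

### Multivariable MR

With K exposures on J shared instruments, Γ̂ is regressed on the J×K
matrix of exposure effects without intercept, weights 1/σyⱼ², giving each
exposure's direct effect. Five estimators: IVW (WLS, overdispersion-
scaled t tests on J−K df); Egger (adds an intercept after orienting rows
on the primary exposure, df J−K−1); median (weighted L1 regression);
LASSO (per-SNP pleiotropy intercepts δⱼ penalized by λΣ|δⱼ|, exposure
coefficients unpenalized); robust (Huber IRLS, tuning 1.345 for 95%
Gaussian efficiency; residuals are standardized by their reported σyⱼ
only, so the fit is exactly IVW whenever no residual exceeds the tuning
bound, and also in the tuning → ∞ limit).

Numerical choices that departed from the most literal reading of the
design sketch, made as this package's own calls:

- *LASSO λ selection.* Shrinking λ only ever moves SNPs out of the valid
  set and lowers its heterogeneity, so "the smallest λ passing a Q
  criterion" degenerates to a near-empty valid set. The implemented rule
  is the published heterogeneity stopping rule: walk a descending
  λ grid from the all-valid limit and keep the first value whose δ = 0
  set has Q at or below the χ² 95th percentile on its df — removing as
  few instruments as the heterogeneity allows. Because that boundary is
  itself a 95th percentile, roughly 5% of clean datasets lose one extra
  SNP; planted gross outliers are nonetheless always excluded in the
  package's planted-truth tests.
- *L1 solver.* IRLS on an L1 objective (weights 1/(|r| + ridge),
  ridge 10⁻⁸) can cycle between near-optimal active sets and converges
  only geometrically in degenerate corners, so the solver tracks the
  best-objective iterate and stops on relative objective stagnation
  (10⁻¹⁰, five stalled iterations, cap 500); it raises with the iterate
  trace only if the objective is still genuinely improving at the cap.
- *Rank handling.* The weighted design is rank-checked before any fit;
  failure names a minimal set of columns expressible as combinations of
  the others (pulse pressure given systolic and diastolic pressure being
  the canonical case) and the guidance is to drop the derived exposure —
  the pipeline's adjusted-MVMR runner surfaces this per confounder
  subset instead of aborting.

### Instrument selection

Genome-wide significance is a strict p < 5×10⁻⁸; clumping greedily keeps
the smallest-p SNP (ties: larger |β|, then lexicographic id — fully
deterministic) and discards everything with r² strictly above 0.001
against a retained SNP, consuming an explicit LD matrix rather than a
genotype panel so behaviour is exactly testable. Instrument strength is
the per-SNP F = (γ̂/σx)², filtered at F > 10. Variance explained offers
both parameterizations in use — 2·eaf·(1−eaf)·γ̂² for trait-SD effects
and F/(F + n − 2) as a unit-free fallback — and records which was used.
The confounder screen consumes a local snp→(trait, p) catalog (the
package's stand-in for an online phenotype-scan service) and excludes a
SNP when it, or any SNP at r² ≥ 0.8 to it, carries a confounder
association at p < 10⁻⁵.

### Harmonization

Matching is by variant id (the sources this design targets are
rsid-keyed). Swapped alleles negate the outcome beta and complement its
frequency; complementary-strand matches are complemented first.
Palindromic (A/T, C/G) SNPs default to frequency inference with a ±0.08
window around 0.5 — kept only when both GWAS report the minor allele
clearly and consistently — with `drop_all` available for strictness.
Sign flips never alter magnitudes or SEs, and the audit counts satisfy
exposure SNPs = retained + dropped-palindromic + dropped-unmatched on
every run.

## The synthetic-data generator

Traits are standardized to unit variance so per-SNP sampling SEs have the
closed form σ = 1/√(2·n·maf(1−maf)); a binary outcome's SE is inflated by
1/√(cf(1−cf)) with cf the case fraction — a deliberate approximation to
logistic-GWAS standard errors, adequate for calibration studies. Truth
per SNP: maf ~ Uniform(maf_range); γⱼ from a Normal(0, gamma_sd²) with
the effect allele reported on the exposure-increasing orientation
(γⱼ ≥ 0), matching how real instrument lists are published — and
necessary for "directional" pleiotropy to be directional: after Egger's
γ̂ ≥ 0 orientation, pleiotropy attached to an unoriented allele coding
would average to zero. Horizontal pleiotropy αⱼ ~ N(μ_α, σ_α²) on a
round(J·fraction) subset, optionally correlated with instrument strength
(`inside_violation_rho`) to break InSIDE; then
γ̂ⱼ = γⱼ + noise, Γ̂ⱼ = θγⱼ + αⱼ + noise. LD is block-diagonal with
r² = ρ^(2|i−j|) within blocks. One global seed drives named RNG streams,
so adding a stream never perturbs existing draws, and identifiers default
to a seed-derived prefix (override `snp_prefix` to make traits share
instruments).

Defaults — J = 50 instruments, exposure and outcome GWAS of 100,000,
gamma_sd = 0.05 (median F in the tens), maf in (0.05, 0.5), no
pleiotropy, θ = 0 — describe a well-powered modern two-sample study and
are the conditions under which the calibration results below are
computed. What the generator does *not* emulate: realistic allele-
frequency spectra, sample overlap between the two GWAS, linkage between
instrument and confounder loci, binary-trait liability-scale effects, or
population stratification. Passing tests therefore demonstrate
correctness of the estimators under the stated sampling model, not
immunity to those real-data complications.

## The packaged study scenario

`mrforge.scenario.run_study` wires a study shaped like a real multi-
exposure analysis: four glycemic exposures (a diabetes-liability analog
with 150 instruments from a 900k-sample GWAS, plus fasting glucose,
fasting insulin and HbA1c analogs at 197k) against a rare primary
outcome (967 cases among 383k), a rarer validation outcome (127 cases)
and a common positive control (64k cases among 341k) with known harmful
log-ORs between ln 1.12 and ln 1.91. The generative truth is null on the
primary and validation outcomes. Each exposure-outcome pair is simulated
as an independent two-sample pair (pairwise-independent GWAS; the
scenario does not reuse one exposure GWAS across outcomes). Significance
calls in the summary table are made on the primary IVW estimate at a
Bonferroni threshold of α/n_tests with n_tests = 45 by default
(0.05/45 ≈ 1.11×10⁻³); the family size is a configuration value, not
something the package infers. The expected qualitative pattern — no
null-outcome estimate past the Bonferroni bar, every control estimate
significant and harm-directed — is what the acceptance script checks.

## Validation problem sizes

`scripts/acceptance.py` computes, per seed: IVW type-I error and
(separately) mean estimate and CI coverage at θ = 0.2, 500 replicates
each at the generator defaults; Egger intercept recovery with μ_α = 0.05,
σ_α = 0.01, J = 100 on 10⁶-sample GWAS (the intercept's consistency
requires small exposure-side sampling noise; residual orientation error
leaves a few percent of attenuation), 300 replicates; MR-PRESSO recovery
of two planted ±8σ outliers among J = 50 with n_sim = 1,000, 150 runs;
weighted-median-beats-IVW rate with 30% invalid instruments
(μ_α = 0.1), 300 replicates; greedy-vs-exhaustive clumping agreement on
500 random instances of up to 12 SNPs; the scenario pattern; and the
Bonferroni threshold for a 45-test family. The dedicated test suite runs
the same checks at its own replicate counts with fixed seeds. These sizes
keep a full validation pass within minutes on one CPU while leaving
Monte-Carlo error well inside the asserted bands.

## Known limitations

- No weak-instrument corrections (the F filter is the only guard); IVW
  attenuation of order 1/F̄ is visible in the recovery numbers.
- MVMR offers no conditional F statistics; instrument strength must be
  judged per exposure upstream.
- No proxy-SNP substitution for unmatched instruments, no physical-
  distance clumping windows, no VCF/BGEN ingestion, and no figure
  rendering — funnel/leave-one-out outputs are plotting-ready tables.
- The distortion test's random-subset null is conditional on the flagged
  set's size; with very few instruments it is coarse.
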