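"""Heterogeneity, pleiotropy, influence and outlier diagnostics.

* Cochran's Q: weighted heterogeneity of the per-SNP Wald ratios around a
  reference causal estimate; Q far above its J−1 degrees of freedom points
  to invalid instruments.
* Egger intercept test: directional (unbalanced) horizontal pleiotropy.
* Leave-one-out: the IVW estimate refit with each instrument omitted, to
  spot single SNPs driving the result.
* MR-PRESSO: a simulation-based residual-sum-of-squares test with global
  (any pleiotropy), outlier (which SNPs) and distortion (does removing
  them change the estimate) components.
* Funnel data: per-SNP ratio vs precision, the numbers behind a funnel
  plot; asymmetry suggests directional pleiotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .estimators import MREstimate, Z_95, ivw, mr_egger
from .exceptions import InsufficientInstrumentsError
from .harmonization import HarmonizedSet

__all__ = [
    "HeterogeneityReport", "PressoResult", "cochran_q", "egger_intercept_test",
    "leave_one_out", "mr_presso", "funnel_data",
]


@dataclass(frozen=True)
class HeterogeneityReport:
    Q: float
    df: int
    pvalue: float

    def to_dict(self) -> dict:
        return {"Q": self.Q, "df": self.df, "pvalue": self.pvalue}


@dataclass
class PressoResult:
    """MR-PRESSO global / outlier / distortion results."""

    global_rss: float
    global_p: float
    n_sim: int
    outliers: pd.DataFrame          #: snp_id, raw_p, bonferroni_p, flagged
    beta_raw: MREstimate
    beta_corrected: Optional[MREstimate]
    distortion_p: Optional[float]
    status: str = "ok"              #: "ok", "no_outliers", "all_snps_flagged"

    @property
    def flagged_snps(self) -> list[str]:
        return list(self.outliers.loc[self.outliers["flagged"], "snp_id"])

    def to_dict(self) -> dict:
        return {
            "global_rss": self.global_rss, "global_p": self.global_p,
            "n_sim": self.n_sim, "status": self.status,
            "n_flagged": len(self.flagged_snps),
            "flagged_snps": self.flagged_snps,
            "beta_raw": self.beta_raw.beta,
            "beta_corrected":
                None if self.beta_corrected is None else self.beta_corrected.beta,
            "distortion_p": self.distortion_p,
        }


def cochran_q(hset: HarmonizedSet, beta_ref: float) -> HeterogeneityReport:
    """Cochran's Q of the Wald ratios around ``beta_ref``.

    Q = Σ_j w_j (β_j − beta_ref)² with first-order inverse-variance
    weights w_j = γ̂_j²/σy_j², referred to a chi-square with J−1 degrees
    of freedom.
    """
    if len(hset) < 2:
        raise InsufficientInstrumentsError(
            f"cochran_q needs at least 2 instruments, got {len(hset)}")
    g, _, G, sy = hset.arrays()
    w = g**2 / sy**2
    q = float(np.sum(w * (G / g - beta_ref) ** 2))
    df = len(g) - 1
    return HeterogeneityReport(q, df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(hset: HarmonizedSet) -> MREstimate:
    """The MR-Egger intercept with its t-test p-value.

    An intercept distinguishable from zero is evidence of directional
    horizontal pleiotropy.
    """
    _, intercept = mr_egger(hset)
    return intercept


def leave_one_out(hset: HarmonizedSet, estimator: str = "ivw_fixed") -> pd.DataFrame:
    """IVW refit with each instrument omitted in turn.

    Returns J+1 rows: one per omitted SNP plus an all-SNP row
    (``omitted_snp_id = "<none>"``), with columns beta, se, pvalue and an
    ``influential`` flag set when omitting the SNP moves the estimate
    outside the full-set 95% CI or flips its sign.
    """
    if len(hset) < 3:
        raise InsufficientInstrumentsError(
            f"leave_one_out needs at least 3 instruments, got {len(hset)}")
    model = {"ivw_fixed": "fixed", "ivw_random": "random"}.get(estimator)
    if model is None:
        raise InsufficientInstrumentsError(
            f"leave_one_out supports ivw_fixed / ivw_random, got {estimator!r}")
    full = ivw(hset, model=model)
    rows = []
    ids = hset.snp_ids
    for snp in ids:
        sub = hset.subset([s for s in ids if s != snp])
        est = ivw(sub, model=model)
        influential = (est.beta < full.ci_low or est.beta > full.ci_high or
                       (est.beta * full.beta < 0))
        rows.append({"omitted_snp_id": snp, "beta": est.beta, "se": est.se,
                     "pvalue": est.pvalue, "influential": bool(influential)})
    rows.append({"omitted_snp_id": "<none>", "beta": full.beta, "se": full.se,
                 "pvalue": full.pvalue, "influential": False})
    return pd.DataFrame(rows)


def _loo_betas(g, G, sy):
    """Leave-one-out IVW estimates for every SNP, in closed form."""
    w_num = g * G / sy**2
    w_den = g**2 / sy**2
    num, den = w_num.sum(axis=-1, keepdims=True), w_den.sum(axis=-1, keepdims=True)
    return (num - w_num) / (den - w_den)


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
              sig: float = 0.05) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is the weighted residual sum of squares
    RSS = Σ_j (Γ̂_j − β̂_{−j} γ̂_j)²/σy_j², with β̂_{−j} the IVW estimate
    leaving SNP j out.  Its null distribution is simulated by redrawing
    γ̂*_j ~ N(γ̂_j, σx_j) and Γ̂*_j ~ N(β̂_{−j} γ̂_j, σy_j) ``n_sim`` times
    and recomputing the statistic from scratch.  P-values use the
    (1 + #exceedances)/(n_sim + 1) convention, so they are never exactly 0.

    Per-SNP outlier p-values compare each observed weighted squared
    residual with its simulated distribution, Bonferroni-scaled by J; SNPs
    below ``sig`` are flagged.  The distortion test compares the estimate
    shift after removing flagged SNPs against the shifts from removing
    random subsets of the same size.
    """
    J = len(hset)
    if J < 4:
        raise InsufficientInstrumentsError(
            f"mr_presso needs at least 4 instruments, got {J}")
    g, sx, G, sy = hset.arrays()
    rng = stream(seed, "mr_presso")

    beta_loo = _loo_betas(g, G, sy)
    resid_obs = (G - beta_loo * g) ** 2 / sy**2
    rss_obs = float(resid_obs.sum())

    g_sim = rng.normal(g, sx, size=(n_sim, J))
    G_sim = rng.normal(beta_loo * g, sy, size=(n_sim, J))
    beta_loo_sim = _loo_betas(g_sim, G_sim, sy)
    resid_sim = (G_sim - beta_loo_sim * g_sim) ** 2 / sy**2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    raw_p = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1)
    bonf_p = np.minimum(1.0, raw_p * J)
    flagged = bonf_p < sig
    outliers = pd.DataFrame({"snp_id": hset.snp_ids, "raw_p": raw_p,
                             "bonferroni_p": bonf_p, "flagged": flagged})

    beta_raw = ivw(hset, model="fixed")
    n_flag = int(flagged.sum())
    if n_flag == 0:
        return PressoResult(rss_obs, global_p, n_sim, outliers, beta_raw,
                            beta_corrected=None, distortion_p=None,
                            status="no_outliers")
    if n_flag == J:
        return PressoResult(rss_obs, global_p, n_sim, outliers, beta_raw,
                            beta_corrected=None, distortion_p=None,
                            status="all_snps_flagged")

    keep = [s for s, f in zip(hset.snp_ids, flagged) if not f]
    beta_corrected = ivw(hset.subset(keep), model="fixed")
    shift_obs = beta_raw.beta - beta_corrected.beta

    # null for the distortion test: remove random same-size subsets
    w_num, w_den = g * G / sy**2, g**2 / sy**2
    num_tot, den_tot = w_num.sum(), w_den.sum()
    shifts = np.empty(n_sim)
    for b in range(n_sim):
        drop = rng.choice(J, size=n_flag, replace=False)
        shifts[b] = beta_raw.beta - ((num_tot - w_num[drop].sum()) /
                                     (den_tot - w_den[drop].sum()))
    distortion_p = float((1 + np.sum(np.abs(shifts) >= abs(shift_obs))) / (n_sim + 1))
    return PressoResult(rss_obs, global_p, n_sim, outliers, beta_raw,
                        beta_corrected, distortion_p, status="ok")


def funnel_data(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratio and precision (1/se), ready for a funnel plot."""
    if len(hset) < 1:
        raise InsufficientInstrumentsError("funnel_data needs at least 1 SNP")
    g, _, G, sy = hset.arrays()
    beta_j = G / g
    se_j = sy / np.abs(g)
    return pd.DataFrame({"snp_id": hset.snp_ids, "beta_j": beta_j,
                         "precision": 1.0 / se_j})
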