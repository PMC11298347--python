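"""Univariable Mendelian randomization estimators.

Given J harmonized instruments with SNP-exposure effects γ̂_j (SE σx_j) and
SNP-outcome effects Γ̂_j (SE σy_j), each estimator targets the causal
effect θ of the exposure on the outcome:

* Wald ratio per SNP: β_j = Γ̂_j / γ̂_j
* inverse-variance-weighted (IVW) meta-analysis of the ratios — identical
  to weighted least squares of Γ̂ on γ̂ through the origin with weights
  1/σy² — in fixed-effect or multiplicative random-effect form
* MR-Egger: the same regression with a free intercept; the slope remains
  consistent under directional pleiotropy satisfying the InSIDE condition
  and the intercept measures the average pleiotropic effect
* weighted median: consistent when instruments carrying ≥ 50% of the
  weight are valid
* mode-based estimate (simple and weighted): the mode of the
  kernel-smoothed Wald-ratio distribution, consistent when the largest
  homogeneous group of instruments is valid

Bootstrap standard errors (median and mode) resample γ̂_j and Γ̂_j from
their sampling distributions and are reproducible given a seed.
For a binary outcome, estimates on the log-odds scale are reported with
odds-ratio equivalents via :func:`to_odds_scale`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from ._rng import stream
from .exceptions import (DegenerateInstrumentError, InputError,
                         InsufficientInstrumentsError)
from .harmonization import HarmonizedPair, HarmonizedSet

__all__ = [
    "RatioEstimate", "MREstimate", "wald_ratio", "ratio_estimates", "ivw",
    "mr_egger", "weighted_median", "simple_median", "mode_estimate",
    "to_odds_scale", "Z_95",
]

#: two-sided 95% normal quantile, fixed for reproducibility
Z_95 = 1.959964


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with its standard error and inverse-variance weight."""

    snp_id: str
    beta_j: float
    se_j: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se_j**2


@dataclass
class MREstimate:
    """One estimator's causal-effect result.

    ``beta`` is on the outcome's beta scale (log odds ratio for a binary
    outcome); ``or_scale`` holds (OR, OR CI low, OR CI high) when set by
    :func:`to_odds_scale`.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    or_scale: Optional[tuple] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"method": self.method, "n_snps": self.n_snps, "beta": self.beta,
             "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
             "pvalue": self.pvalue}
        if self.or_scale is not None:
            d["or"], d["or_ci_low"], d["or_ci_high"] = self.or_scale
        return d


def _normal_estimate(method, beta, se, n_snps, **extra) -> MREstimate:
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    p = float(min(max(p, 5e-324), 1.0))
    return MREstimate(method, float(beta), float(se), float(beta - Z_95 * se),
                      float(beta + Z_95 * se), p, int(n_snps), extra=dict(extra))


def _t_estimate(method, beta, se, df, n_snps, **extra) -> MREstimate:
    p = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else (1.0 if beta == 0 else 0.0)
    p = float(min(max(p, 5e-324), 1.0))
    return MREstimate(method, float(beta), float(se), float(beta - Z_95 * se),
                      float(beta + Z_95 * se), p, int(n_snps),
                      extra=dict(extra, df=df))


def wald_ratio(pair: HarmonizedPair, se_order: str = "first") -> RatioEstimate:
    """Single-SNP causal estimate β_j = Γ̂_j / γ̂_j.

    ``se_order="first"`` (default) gives se_j = σy_j/|γ̂_j|, the delta-method
    SE ignoring exposure-side noise; ``"second"`` adds the exposure term:
    sqrt(σy²/γ̂² + Γ̂²σx²/γ̂⁴).
    """
    if pair.gamma_hat == 0:
        raise DegenerateInstrumentError(
            f"SNP {pair.snp_id}: zero exposure effect, Wald ratio undefined")
    beta_j = pair.Gamma_hat / pair.gamma_hat
    if se_order == "first":
        se_j = pair.sigma_y / abs(pair.gamma_hat)
    elif se_order == "second":
        se_j = math.sqrt(pair.sigma_y**2 / pair.gamma_hat**2 +
                         pair.Gamma_hat**2 * pair.sigma_x**2 / pair.gamma_hat**4)
    else:
        raise InputError(f"se_order must be 'first' or 'second', got {se_order!r}")
    return RatioEstimate(pair.snp_id, float(beta_j), float(se_j))


def ratio_estimates(hset: HarmonizedSet, se_order: str = "first") -> list[RatioEstimate]:
    return [wald_ratio(p, se_order) for p in hset.pairs]


def _require(hset: HarmonizedSet, minimum: int, method: str) -> None:
    if len(hset) < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {minimum} instruments, got {len(hset)}")
    if any(p.gamma_hat == 0 for p in hset.pairs):
        raise DegenerateInstrumentError(f"{method}: zero exposure effect present")


def _ivw_point(g, sy, G):
    w = g**2 / sy**2
    return float(np.sum(w * (G / g)) / np.sum(w)), w


def ivw(hset: HarmonizedSet, model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    Weights w_j = γ̂_j²/σy_j² (the inverse variance of the first-order
    ratio SE), making the estimate identical to weighted least squares of
    Γ̂ on γ̂ through the origin with weights 1/σy_j².  ``model="fixed"``
    uses SE = (Σw)^{-1/2}; ``"random"`` inflates it multiplicatively by
    max(1, sqrt(Q/(J−1))) with Cochran's Q taken at the IVW estimate.
    P-values are two-sided normal.
    """
    if model not in ("fixed", "random"):
        raise InputError(f"ivw model must be 'fixed' or 'random', got {model!r}")
    _require(hset, 1 if model == "fixed" else 2, f"ivw_{model}")
    g, sx, G, sy = hset.arrays()
    beta, w = _ivw_point(g, sy, G)
    se = float(np.sum(w) ** -0.5)
    extra = {}
    if model == "random":
        q = float(np.sum(w * (G / g - beta) ** 2))
        scale = max(1.0, math.sqrt(q / (len(g) - 1)))
        se *= scale
        extra = {"Q": q, "overdispersion": scale}
    return _normal_estimate(f"ivw_{model}", beta, se, len(g), **extra)


def mr_egger(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: returns (slope, intercept) estimates.

    Each SNP is oriented so γ̂_j ≥ 0 (negating both effects where needed),
    then Γ̂ is regressed on γ̂ with an intercept, weights 1/σy_j².  SEs
    carry a multiplicative overdispersion factor bounded below by 1 and
    p-values use a t reference with J−2 degrees of freedom.  The slope is
    the causal estimate; a nonzero intercept indicates directional
    horizontal pleiotropy.
    """
    _require(hset, 3, "mr_egger")
    g, sx, G, sy = hset.arrays()
    flip = np.where(g < 0, -1.0, 1.0)
    g, G = g * flip, G * flip
    if np.ptp(g) == 0:
        raise InputError("mr_egger: all exposure effects identical after "
                         "orientation; slope and intercept are not identifiable")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(g), g])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], G * sw, rcond=None)
    resid = G - X @ coef
    J = len(g)
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss_w / (J - 2)))
    xtx_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    se0, se1 = scale * np.sqrt(np.diag(xtx_inv))
    slope = _t_estimate("egger_slope", coef[1], se1, J - 2, J,
                        overdispersion=scale)
    intercept = _t_estimate("egger_intercept", coef[0], se0, J - 2, J,
                            overdispersion=scale)
    return slope, intercept


def _weighted_median_point(betas: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates."""
    order = np.argsort(betas, kind="stable")
    b, p = betas[order], weights[order] / weights.sum()
    s = np.cumsum(p) - 0.5 * p
    return float(np.interp(0.5, s, b))


def _bootstrap_se(hset, point_fn, n_boot, seed, name):
    """Parametric bootstrap SE: resample γ̂, Γ̂ from their sampling laws."""
    g, sx, G, sy = hset.arrays()
    rng = stream(seed, name)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        g_b = rng.normal(g, sx)
        G_b = rng.normal(G, sy)
        reps[b] = point_fn(g_b, G_b, sy)
    return float(np.std(reps, ddof=1)), reps


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0, weighted: bool = True) -> MREstimate:
    """Weighted (or simple) median of the Wald ratios.

    The ratios are sorted; with normalized weights p_j the cumulative
    midpoint s_j = Σ_{k≤j} p_k − p_j/2 is computed and the estimate is the
    linear interpolation of β at s = 0.5.  ``weighted=False`` uses equal
    weights (the simple median).  The SE is the standard deviation of
    ``n_boot`` parametric-bootstrap replicates; the CI is normal-based.
    """
    _require(hset, 3, "weighted_median")

    def point(g_b, G_b, sy_b):
        b = G_b / g_b
        w = (g_b**2 / sy_b**2) if weighted else np.ones_like(b)
        return _weighted_median_point(b, w)

    g, sx, G, sy = hset.arrays()
    beta = point(g, G, sy)
    method = "weighted_median" if weighted else "simple_median"
    se, _ = _bootstrap_se(hset, point, n_boot, seed, method)
    return _normal_estimate(method, beta, se, len(hset), n_boot=n_boot)


def simple_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    return weighted_median(hset, n_boot=n_boot, seed=seed, weighted=False)


def _mode_point(betas, weights, phi, min_grid=512, max_grid=8192):
    """Argmax of the normal-kernel-smoothed, weighted ratio density.

    The grid spans the ratio range padded by 3h with at least ``min_grid``
    points; when stray extreme ratios stretch the range the grid is
    refined (up to ``max_grid``) so its spacing stays well below the
    bandwidth and the argmax is not quantization noise.
    """
    J = len(betas)
    sd = float(np.std(betas, ddof=1)) if J > 1 else 0.0
    mad = float(np.median(np.abs(betas - np.median(betas)))) * 1.4826
    h = phi * 0.9 * min(sd, mad) * J ** (-1 / 5)
    if h <= 0:
        # all ratios (effectively) identical: the mode is that common value
        return float(np.median(betas))
    span = (betas.max() - betas.min()) + 6 * h
    n_grid = int(np.clip(np.ceil(span / (h / 10)), min_grid, max_grid))
    grid = np.linspace(betas.min() - 3 * h, betas.max() + 3 * h, n_grid)
    p = weights / weights.sum()
    dens = np.exp(-0.5 * ((grid[:, None] - betas[None, :]) / h) ** 2) @ p
    return float(grid[np.argmax(dens)])


def mode_estimate(hset: HarmonizedSet, weighted: bool = False, phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode-based causal estimate (simple or inverse-variance weighted).

    Wald ratios are smoothed with a normal kernel of bandwidth
    h = phi · 0.9 · min(sd(β), 1.4826·MAD(β)) · J^{−1/5} and the estimate
    is the argmax of the smoothed density on a grid of at least 512 points
    spanning the ratio range padded by 3h (refined automatically when
    outlying ratios stretch the range).  When every ratio coincides the
    common value is returned directly.  SE by seeded parametric bootstrap.
    """
    _require(hset, 3, "mode_estimate")

    def point(g_b, G_b, sy_b):
        b = G_b / g_b
        w = (g_b**2 / sy_b**2) if weighted else np.ones_like(b)
        return _mode_point(b, w, phi)

    g, sx, G, sy = hset.arrays()
    beta = point(g, G, sy)
    method = "weighted_mode" if weighted else "simple_mode"
    se, _ = _bootstrap_se(hset, point, n_boot, seed, method)
    return _normal_estimate(method, beta, se, len(hset), n_boot=n_boot, phi=phi)


def to_odds_scale(estimate: MREstimate, outcome_type: str = "binary") -> MREstimate:
    """Attach odds-ratio-scale fields exp(beta), exp(ci) for binary outcomes.

    For a quantitative outcome this is a no-op (the beta is not a log odds
    ratio) and a warning is recorded on the estimate.
    """
    if outcome_type != "binary":
        out = replace(estimate)
        out.extra = dict(estimate.extra,
                         warning="quantitative outcome: no odds-ratio scale")
        return out
    out = replace(estimate)
    out.or_scale = (math.exp(estimate.beta), math.exp(estimate.ci_low),
                    math.exp(estimate.ci_high))
    out.extra = dict(estimate.extra)
    return out


def all_estimators(hset: HarmonizedSet, n_boot: int = 1000,
                   seed: int = 0) -> list[MREstimate]:
    """The study's univariable battery: IVW (primary), MR-Egger slope and
    intercept, weighted median, simple mode and weighted mode, each on the
    odds-ratio scale when the outcome is binary."""
    slope, intercept = mr_egger(hset)
    ests = [
        ivw(hset, model="fixed"),
        slope, intercept,
        weighted_median(hset, n_boot=n_boot, seed=seed),
        mode_estimate(hset, weighted=False, n_boot=n_boot, seed=seed),
        mode_estimate(hset, weighted=True, n_boot=n_boot, seed=seed),
    ]
    return [to_odds_scale(e, hset.outcome_type) for e in ests]
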