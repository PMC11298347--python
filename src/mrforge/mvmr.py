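"""Multivariable Mendelian randomization (MVMR).

With K ≥ 2 exposures measured on the same J instruments, the per-SNP
outcome effects are regressed jointly on the K exposure-effect columns
(weights 1/σy_j², no intercept), so each exposure's coefficient is its
direct effect on the outcome conditional on the others.  Five estimators
are provided, mirroring common practice:

* IVW (weighted least squares)
* Egger (adds an intercept after orienting SNPs on the primary exposure)
* median (weighted L1 regression, robust to up to half-weight invalidity)
* LASSO (per-SNP pleiotropy intercepts δ_j with an L1 penalty; SNPs whose
  δ_j is shrunk to zero form the valid set, re-fit by IVW)
* robust (Huber-weighted IVW)

A deliberately collinear exposure set — e.g. pulse pressure together with
systolic and diastolic blood pressure, of which it is an exact difference
at the per-SNP beta level — fails the rank check with the offending
columns named; the remedy is to drop the derived exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from ._rng import stream
from .estimators import MREstimate, Z_95, _t_estimate
from .exceptions import (ConfigurationError, ConvergenceError, InputError,
                         InsufficientInstrumentsError, RankDeficiencyError)

__all__ = ["MVMRInput", "mvmr_ivw", "mvmr_egger", "mvmr_median", "mvmr_lasso",
           "mvmr_robust", "all_mvmr_estimators"]

_RANK_RCOND = 1e-10


@dataclass
class MVMRInput:
    """Joint instrument data for K exposures and one outcome."""

    snp_ids: list
    exposure_betas: np.ndarray    #: J×K matrix of γ̂_jk
    exposure_ses: np.ndarray      #: J×K matrix of their SEs
    outcome_betas: np.ndarray     #: J vector Γ̂_j
    outcome_ses: np.ndarray       #: J vector σy_j
    exposure_names: list = field(default_factory=list)
    primary_exposure: int = 0
    outcome_type: str = "binary"

    def __post_init__(self):
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, float))
        self.outcome_betas = np.asarray(self.outcome_betas, float)
        self.outcome_ses = np.asarray(self.outcome_ses, float)
        j, k = self.exposure_betas.shape
        if not self.exposure_names:
            self.exposure_names = [f"exposure_{i}" for i in range(k)]
        if self.exposure_ses.shape != (j, k) or self.outcome_betas.shape != (j,) \
                or self.outcome_ses.shape != (j,):
            raise InputError("MVMR input dimensions do not agree")
        if len(self.snp_ids) != j:
            raise InputError("snp_ids length does not match instrument count")
        if (self.exposure_ses <= 0).any() or (self.outcome_ses <= 0).any():
            raise InputError("all standard errors must be positive")
        if np.isnan(self.exposure_betas).any() or np.isnan(self.outcome_betas).any():
            raise InputError("MVMR input has missing cells; drop incomplete "
                             "SNPs upstream")
        if not 0 <= self.primary_exposure < k:
            raise ConfigurationError("primary_exposure index out of range")

    @property
    def J(self) -> int:
        return self.exposure_betas.shape[0]

    @property
    def K(self) -> int:
        return self.exposure_betas.shape[1]


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X, tol=_RANK_RCOND * max(X.shape) *
                                 np.abs(X).max())
    if rank < X.shape[1]:
        # name a minimal set of columns that are linear combinations of others
        bad = []
        for k in range(X.shape[1]):
            others = np.delete(X, k, axis=1)
            coef, res, *_ = np.linalg.lstsq(others, X[:, k], rcond=None)
            resid = X[:, k] - others @ coef
            if np.abs(resid).max() <= 1e-8 * max(1.0, np.abs(X[:, k]).max()):
                bad.append(names[k] if k < len(names) else f"col{k}")
        raise RankDeficiencyError(
            f"exposure design matrix is rank deficient (rank {rank} < "
            f"{X.shape[1]}); collinear columns: {bad or 'undetermined'} — "
            "drop a derived exposure (e.g. pulse pressure when systolic and "
            "diastolic pressure are both included)", columns=bad)


def _require(inp: MVMRInput, min_extra: int, method: str) -> None:
    if inp.K < 1:
        raise InputError(f"{method}: need at least one exposure")
    if inp.J < inp.K + min_extra:
        raise InsufficientInstrumentsError(
            f"{method} needs J > K{'+1' if min_extra > 1 else ''} "
            f"(J={inp.J}, K={inp.K})")


def _wls(X, y, w):
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def _estimates_from_fit(inp, coef, cov, df, method, **extra):
    ses = np.sqrt(np.diag(cov))
    return [_t_estimate(f"{method}", float(b), float(s), df, inp.J,
                        exposure=name, **extra)
            for name, b, s in zip(inp.exposure_names, coef, ses)]


def mvmr_ivw(inp: MVMRInput) -> list[MREstimate]:
    """Multivariable IVW: WLS of Γ̂ on the exposure-beta columns, no intercept.

    SEs carry a multiplicative overdispersion factor
    max(1, sqrt(Q_mv/(J−K))) from the weighted residual sum of squares;
    p-values use a t reference with J−K degrees of freedom.
    """
    _require(inp, 1, "mvmr_ivw")
    X, y = inp.exposure_betas, inp.outcome_betas
    w = 1.0 / inp.outcome_ses**2
    _check_rank(X * np.sqrt(w)[:, None], inp.exposure_names)
    coef = _wls(X, y, w)
    resid = y - X @ coef
    q_mv = float(np.sum(w * resid**2))
    df = inp.J - inp.K
    scale = max(1.0, math.sqrt(q_mv / df))
    cov = scale**2 * np.linalg.inv(X.T @ (X * w[:, None]))
    return _estimates_from_fit(inp, coef, cov, df, "mvmr_ivw",
                               Q=q_mv, overdispersion=scale)


def mvmr_egger(inp: MVMRInput) -> tuple[list[MREstimate], MREstimate]:
    """Multivariable Egger: WLS with an intercept after orienting SNPs.

    Each SNP is oriented so the primary exposure's γ̂ is non-negative
    (negating the whole row where needed), making the fit invariant to
    arbitrary per-SNP allele sign choices.  Returns (per-exposure
    estimates, intercept); df = J−K−1.
    """
    _require(inp, 2, "mvmr_egger")
    flip = np.where(inp.exposure_betas[:, inp.primary_exposure] < 0, -1.0, 1.0)
    X = inp.exposure_betas * flip[:, None]
    y = inp.outcome_betas * flip
    w = 1.0 / inp.outcome_ses**2
    Xi = np.column_stack([np.ones(inp.J), X])
    _check_rank(Xi * np.sqrt(w)[:, None], ["intercept"] + list(inp.exposure_names))
    coef = _wls(Xi, y, w)
    resid = y - Xi @ coef
    df = inp.J - inp.K - 1
    scale = max(1.0, math.sqrt(float(np.sum(w * resid**2)) / df))
    cov = scale**2 * np.linalg.inv(Xi.T @ (Xi * w[:, None]))
    ses = np.sqrt(np.diag(cov))
    intercept = _t_estimate("mvmr_egger_intercept", float(coef[0]), float(ses[0]),
                            df, inp.J, overdispersion=scale)
    slopes = [_t_estimate("mvmr_egger", float(b), float(s), df, inp.J,
                          exposure=name, overdispersion=scale)
              for name, b, s in zip(inp.exposure_names, coef[1:], ses[1:])]
    return slopes, intercept


def _lad_irls(X, y, a, tol=1e-10, max_iter=500, ridge=1e-8):
    """Weighted L1 regression min Σ a_j|y_j − X_j β| by IRLS.

    IRLS on an L1 objective can cycle between near-optimal active sets, so
    the best-objective iterate is tracked and returned once the objective
    has stopped improving; a genuine failure to settle raises with the
    iterate trace attached.
    """
    beta = _wls(X, y, a**2)          # WLS start
    trace = [beta.copy()]
    best_obj, best_beta, stall = np.inf, beta, 0
    for _ in range(max_iter):
        r = y - X @ beta
        w = a / (np.abs(r) + ridge)
        beta_new = _wls(X, y, w)
        trace.append(beta_new.copy())
        delta = np.abs(beta_new - beta).max()
        obj = float(np.sum(a * np.abs(y - X @ beta_new)))
        if not np.isfinite(best_obj) or obj < best_obj - 1e-10 * max(1.0, best_obj):
            best_obj, best_beta, stall = obj, beta_new, 0
        else:
            stall += 1
        beta = beta_new
        if delta < tol or stall >= 5:
            return best_beta, trace
    raise ConvergenceError(
        f"weighted-median IRLS still improving after {max_iter} iterations "
        f"(last coefficient change {delta:.3e})", trace=trace)


def mvmr_median(inp: MVMRInput, n_boot: int = 1000, seed: int = 0) -> list[MREstimate]:
    """Multivariable weighted median: L1 regression of Γ̂ on the exposures.

    Minimizes Σ_j |Γ̂_j − Σ_k β_k γ̂_jk| / σy_j by iteratively reweighted
    least squares; SEs by seeded parametric bootstrap resampling both the
    exposure and outcome betas from their sampling distributions.
    """
    _require(inp, 1, "mvmr_median")
    X, y = inp.exposure_betas, inp.outcome_betas
    a = 1.0 / inp.outcome_ses
    _check_rank(X * a[:, None], inp.exposure_names)
    beta, _ = _lad_irls(X, y, a)
    rng = stream(seed, "mvmr_median")
    reps = np.empty((n_boot, inp.K))
    for b in range(n_boot):
        Xb = rng.normal(X, inp.exposure_ses)
        yb = rng.normal(y, inp.outcome_ses)
        try:
            reps[b], _ = _lad_irls(Xb, yb, a)
        except ConvergenceError:
            reps[b] = np.nan
    ses = np.nanstd(reps, axis=0, ddof=1)
    df = inp.J - inp.K
    return [_t_estimate("mvmr_median", float(bk), float(sk), df, inp.J,
                        exposure=name, n_boot=n_boot)
            for name, bk, sk in zip(inp.exposure_names, beta, ses)]


def mvmr_lasso(inp: MVMRInput, lambda_grid=None,
               n_lambda: int = 50) -> tuple[list[MREstimate], list, dict]:
    """MVMR-LASSO: per-SNP pleiotropy intercepts with an L1 penalty.

    Model Γ̂_j = Σ_k β_k γ̂_jk + δ_j, weights w_j = 1/σy_j²; the exposure
    coefficients are unpenalized while λΣ|δ_j| shrinks the per-SNP
    intercepts.  For each λ (descending grid, automatic if not given) the
    problem is solved by alternating WLS on β with soft-thresholding on δ.
    λ is chosen by a heterogeneity stopping rule: walking the grid down
    from the all-valid limit, the first λ whose δ=0 SNPs ("valid set")
    give heterogeneity Q at or below the chi-square 95th percentile on
    their degrees of freedom is kept — removing as few SNPs as the
    heterogeneity allows.  The final estimates are the plain MVMR-IVW fit
    on that valid set.

    Returns (estimates, valid_snp_ids, info); ``info["status"]`` is
    ``"fallback_largest_lambda"`` when no grid value meets the criterion.
    """
    _require(inp, 1, "mvmr_lasso")
    X, y = inp.exposure_betas, inp.outcome_betas
    w = 1.0 / inp.outcome_ses**2
    _check_rank(X * np.sqrt(w)[:, None], inp.exposure_names)

    beta0 = _wls(X, y, w)
    r0 = y - X @ beta0
    lam_max = float(np.max(2.0 * w * np.abs(r0)))
    if lambda_grid is None:
        if lam_max == 0:
            lambda_grid = np.array([1.0])
        else:
            lambda_grid = np.geomspace(lam_max * 1.001, lam_max * 1e-3, n_lambda)
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]
        if (lambda_grid <= 0).any():
            raise ConfigurationError(
                "lambda_grid must be positive: at λ = 0 every SNP gets its own "
                "intercept and the exposure effects are not identifiable")

    chosen = None
    fallback = None
    for lam in lambda_grid:
        beta, delta = beta0.copy(), np.zeros(inp.J)
        for _ in range(500):
            r = y - X @ beta
            delta_new = np.sign(r) * np.maximum(np.abs(r) - lam / (2.0 * w), 0.0)
            beta_new = _wls(X, y - delta_new, w)
            if (np.abs(beta_new - beta).max() < 1e-10 and
                    np.abs(delta_new - delta).max() < 1e-10):
                beta, delta = beta_new, delta_new
                break
            beta, delta = beta_new, delta_new
        valid = delta == 0.0
        if fallback is None:
            fallback = (lam, valid.copy())
        df_valid = int(valid.sum()) - inp.K
        if df_valid < 1:
            continue
        sub = _subset(inp, valid)
        resid = sub.outcome_betas - sub.exposure_betas @ _wls(
            sub.exposure_betas, sub.outcome_betas, 1.0 / sub.outcome_ses**2)
        q = float(np.sum(resid**2 / sub.outcome_ses**2))
        if q <= stats.chi2.ppf(0.95, df_valid):
            chosen = (lam, valid.copy())   # first passing λ on the descending grid
            break

    if chosen is None:
        lam, valid = fallback
        status = "fallback_largest_lambda"
    else:
        lam, valid = chosen
        status = "ok"
    sub = _subset(inp, valid)
    estimates = mvmr_ivw(sub)
    for e in estimates:
        e.method = "mvmr_lasso"
        e.extra.update({"lambda": float(lam), "n_valid": int(valid.sum()),
                        "status": status})
    valid_ids = [s for s, v in zip(inp.snp_ids, valid) if v]
    return estimates, valid_ids, {"lambda": float(lam), "status": status,
                                  "valid": valid}


def _subset(inp: MVMRInput, mask) -> MVMRInput:
    mask = np.asarray(mask, bool)
    return MVMRInput(
        snp_ids=[s for s, m in zip(inp.snp_ids, mask) if m],
        exposure_betas=inp.exposure_betas[mask],
        exposure_ses=inp.exposure_ses[mask],
        outcome_betas=inp.outcome_betas[mask],
        outcome_ses=inp.outcome_ses[mask],
        exposure_names=list(inp.exposure_names),
        primary_exposure=inp.primary_exposure,
        outcome_type=inp.outcome_type)


def mvmr_robust(inp: MVMRInput, tuning: float = 1.345, tol: float = 1e-10,
                max_iter: int = 100) -> list[MREstimate]:
    """Huber-weighted MVMR: IRLS downweighting large standardized residuals.

    Residuals are standardized by their reported SEs, u_j = r_j/σy_j, and
    Huber weights min(1, tuning/|u_j|) multiply the base 1/σy² weights —
    so when no residual exceeds ``tuning`` standard errors the fit is
    exactly MVMR-IVW.  The default tuning constant 1.345 gives 95%
    efficiency under Gaussian residuals; tuning → ∞ also reduces to IVW.
    """
    _require(inp, 1, "mvmr_robust")
    X, y = inp.exposure_betas, inp.outcome_betas
    w0 = 1.0 / inp.outcome_ses**2
    _check_rank(X * np.sqrt(w0)[:, None], inp.exposure_names)
    beta = _wls(X, y, w0)
    trace = [beta.copy()]
    for _ in range(max_iter):
        u = (y - X @ beta) * np.sqrt(w0)
        h = np.minimum(1.0, tuning / np.maximum(np.abs(u), 1e-300))
        beta_new = _wls(X, y, w0 * h)
        trace.append(beta_new.copy())
        if np.abs(beta_new - beta).max() < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        raise ConvergenceError(
            f"mvmr_robust IRLS did not converge in {max_iter} iterations",
            trace=trace)
    resid = y - X @ beta
    wh = w0 * h
    df = inp.J - inp.K
    q_h = float(np.sum(wh * resid**2))
    scale = max(1.0, math.sqrt(q_h / df))
    cov = scale**2 * np.linalg.inv(X.T @ (X * wh[:, None]))
    return _estimates_from_fit(inp, beta, cov, df, "mvmr_robust",
                               tuning=tuning)


def all_mvmr_estimators(inp: MVMRInput, n_boot: int = 1000,
                        seed: int = 0) -> dict:
    """Run the five-method multivariable battery on one input."""
    slopes, intercept = mvmr_egger(inp)
    lasso_est, valid_ids, lasso_info = mvmr_lasso(inp)
    return {
        "ivw": mvmr_ivw(inp),
        "egger": slopes,
        "egger_intercept": intercept,
        "median": mvmr_median(inp, n_boot=n_boot, seed=seed),
        "lasso": lasso_est,
        "lasso_valid_snps": valid_ids,
        "robust": mvmr_robust(inp),
    }
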