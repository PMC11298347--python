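"""End-to-end study orchestration.

Wires the stages of a summary-statistics MR study into configured,
seeded, fully audited runs:

1. univariable MR per exposure-outcome pair: significance filter, LD
   clumping, instrument-strength statistics, optional confounder-trait
   screen ("adjustment group"), harmonization, the six-estimator battery
   and every sensitivity diagnostic;
2. a confounder screen classifying candidate factors by whether they
   causally associate with the exposure, the outcome, both (confounder)
   or neither;
3. multivariable MR passes adjusting for chosen confounder subsets, with
   collinear subsets surfacing a named rank error rather than silently
   degrading;
4. a positive-control run that must recover a known harmful effect;
5. Bonferroni-corrected significance calls across the analysis family.

Every stage records SNP counts so the ledger balances: each input SNP is
retained or excluded by exactly one stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import child_seed
from .estimators import all_estimators, ivw, to_odds_scale
from .exceptions import ConfigurationError, InputError, RankDeficiencyError
from .harmonization import HarmonizedSet, harmonize_sets
from .instruments import (InstrumentConfig, LDMatrix, TraitCatalog,
                          f_statistics, filter_by_pvalue, ld_clump,
                          screen_pleiotropy, variance_explained)
from .mvmr import MVMRInput, all_mvmr_estimators
from .sensitivity import cochran_q, egger_intercept_test, funnel_data, \
    leave_one_out, mr_presso
from .sumstats_io import SummaryStatsTable

__all__ = [
    "bonferroni_threshold", "UnivariableResult", "run_univariable",
    "ScreenResult", "run_confounder_screen", "build_mvmr_input",
    "run_adjusted_mvmr", "run_positive_control",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ConfigurationError(f"n_tests must be >= 1, got {n_tests}")
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha / n_tests


@dataclass
class UnivariableResult:
    """Full result bundle for one exposure-outcome univariable analysis."""

    exposure: str
    outcome: str
    status: str                       #: "ok" or "underpowered"
    counts: dict                      #: SNP ledger per stage
    estimates: list = field(default_factory=list)
    heterogeneity: Optional[object] = None
    egger_intercept: Optional[object] = None
    loo: Optional[pd.DataFrame] = None
    presso: Optional[object] = None
    funnel: Optional[pd.DataFrame] = None
    r2: Optional[dict] = None
    f_stats: Optional[pd.Series] = None
    harmonized: Optional[HarmonizedSet] = None
    screen_exclusions: list = field(default_factory=list)

    def estimate(self, method: str):
        for e in self.estimates:
            if e.method == method:
                return e
        raise KeyError(method)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.estimates])


def _select_instruments(exposure, config, ld):
    counts = {"input": len(exposure)}
    sig = filter_by_pvalue(exposure, config.p_threshold)
    counts["failed_p_threshold"] = counts["input"] - len(sig)
    if ld is not None and len(sig) > 0:
        clumped = ld_clump(sig, ld, config.clump_r2)
    else:
        clumped = sig
    counts["removed_by_clumping"] = len(sig) - len(clumped)
    f = f_statistics(clumped)
    strong = clumped.subset((f > config.f_min).to_numpy())
    counts["weak_instruments"] = len(clumped) - len(strong)
    return strong, f, counts


def run_univariable(exposure: SummaryStatsTable, outcome: SummaryStatsTable,
                    instrument_config: Optional[InstrumentConfig] = None,
                    seed: int = 0, ld: Optional[LDMatrix] = None,
                    catalog: Optional[TraitCatalog] = None,
                    confounder_traits: Sequence[str] = (),
                    palindrome_policy: str = "infer_by_eaf",
                    n_boot: int = 1000, n_sim: int = 1000):
    """Run the full univariable battery for one exposure-outcome pair.

    Returns the primitive-group :class:`UnivariableResult`; when a trait
    catalog and confounder list are supplied, returns
    ``(primitive_result, adjusted_result)`` where the adjusted ("adjustment
    group") run repeats the analysis on the pleiotropy-screened instrument
    set.  With fewer than 3 surviving instruments the bundle carries
    ``status="underpowered"`` instead of raising.
    """
    config = instrument_config or InstrumentConfig()
    strong, f, counts = _select_instruments(exposure, config, ld)

    def analyse(table, counts, screen_exclusions=()):
        hset = harmonize_sets(table, outcome, palindrome_policy=palindrome_policy)
        counts = dict(counts, **{f"harmonization_{k}": v
                                 for k, v in hset.audit.items()})
        counts["analysed"] = len(hset)
        res = UnivariableResult(exposure.trait_name, outcome.trait_name,
                                status="ok", counts=counts,
                                screen_exclusions=list(screen_exclusions))
        try:
            res.r2 = {k: v for k, v in variance_explained(table).items()
                      if k != "per_snp"}
        except InputError:
            res.r2 = None
        res.f_stats = f_statistics(table)
        if len(hset) < 3:
            res.status = "underpowered"
            return res
        res.harmonized = hset
        res.estimates = all_estimators(hset, n_boot=n_boot,
                                       seed=child_seed(seed, "estimators"))
        beta_ivw = res.estimate("ivw_fixed").beta
        res.heterogeneity = cochran_q(hset, beta_ivw)
        res.egger_intercept = res.estimate("egger_intercept")
        res.loo = leave_one_out(hset)
        if len(hset) >= 4:
            res.presso = mr_presso(hset, n_sim=n_sim,
                                   seed=child_seed(seed, "presso"))
        res.funnel = funnel_data(hset)
        return res

    primitive = analyse(strong, counts)
    if catalog is None:
        return primitive

    if not confounder_traits:
        raise ConfigurationError("confounder_traits required when a catalog "
                                 "is supplied")
    screened, exclusions = screen_pleiotropy(
        strong, catalog, confounder_traits, screen_p=config.screen_p,
        proxy_r2=config.proxy_r2, ld=ld)
    counts_adj = dict(counts)
    counts_adj["excluded_by_screen"] = len(exclusions)
    adjusted = analyse(screened, counts_adj, exclusions)
    return primitive, adjusted


@dataclass
class ScreenResult:
    """Per-factor classification from the confounder screen."""

    rows: pd.DataFrame   #: factor, target, beta/p per method, associated flag

    def classification(self) -> pd.DataFrame:
        wide = self.rows.pivot_table(index="factor", columns="target",
                                     values="associated", aggfunc="first")
        out = []
        for factor, row in wide.iterrows():
            exp_a = bool(row.get("exposure", False))
            out_a = bool(row.get("outcome", False))
            label = ("confounder" if exp_a and out_a else
                     "exposure_associated" if exp_a else
                     "outcome_associated" if out_a else "neither")
            out.append({"factor": factor, "classification": label})
        return pd.DataFrame(out)


def _factor_associated(hset: HarmonizedSet, alpha: float, seed: int,
                       n_boot: int, n_sim: int) -> dict:
    """IVW significance with direction-consistent median and PRESSO checks."""
    est_ivw = ivw(hset, model="fixed")
    from .estimators import weighted_median
    est_med = weighted_median(hset, n_boot=n_boot, seed=child_seed(seed, "wm"))
    presso = mr_presso(hset, n_sim=n_sim, seed=child_seed(seed, "presso")) \
        if len(hset) >= 4 else None
    beta_presso = est_ivw.beta
    if presso is not None and presso.beta_corrected is not None:
        beta_presso = presso.beta_corrected.beta
    consistent = (np.sign(est_med.beta) == np.sign(est_ivw.beta) and
                  np.sign(beta_presso) == np.sign(est_ivw.beta))
    return {
        "ivw_beta": est_ivw.beta, "ivw_p": est_ivw.pvalue,
        "median_beta": est_med.beta, "presso_beta": beta_presso,
        "associated": bool(est_ivw.pvalue < alpha and consistent),
        "status": "ok",
    }


def run_confounder_screen(candidate_factors: Mapping[str, SummaryStatsTable],
                          exposure: SummaryStatsTable,
                          outcome: SummaryStatsTable,
                          instrument_config: Optional[InstrumentConfig] = None,
                          alpha: float = 0.05, seed: int = 0,
                          ld: Optional[LDMatrix] = None,
                          n_boot: int = 500, n_sim: int = 500) -> ScreenResult:
    """Classify candidate factors as confounders of the exposure-outcome pair.

    Each factor is analysed as an exposure against both the study exposure
    and the study outcome.  A factor counts as associated with a target
    when its IVW p-value is below ``alpha`` and the weighted-median and
    PRESSO-outlier-corrected estimates agree in sign with IVW.  Factors
    associated with both targets are confounders.  Factors with fewer
    than 3 surviving instruments are classified with an ``underpowered``
    status rather than a silent omission.
    """
    if not candidate_factors:
        raise ConfigurationError("need at least one candidate factor")
    config = instrument_config or InstrumentConfig()
    rows = []
    for i, (name, table) in enumerate(candidate_factors.items()):
        strong, _, _ = _select_instruments(table, config, ld)
        for target_name, target in (("exposure", exposure), ("outcome", outcome)):
            hset = harmonize_sets(strong, target)
            if len(hset) < 3:
                rows.append({"factor": name, "target": target_name,
                             "associated": False, "status": "underpowered",
                             "ivw_beta": np.nan, "ivw_p": np.nan,
                             "median_beta": np.nan, "presso_beta": np.nan})
                continue
            rec = _factor_associated(hset, alpha,
                                     child_seed(seed, f"screen_{name}_{target_name}"),
                                     n_boot, n_sim)
            rows.append({"factor": name, "target": target_name, **rec})
    return ScreenResult(pd.DataFrame(rows))


def build_mvmr_input(exposures: Mapping[str, SummaryStatsTable],
                     outcome: SummaryStatsTable,
                     instrument_config: Optional[InstrumentConfig] = None,
                     ld: Optional[LDMatrix] = None,
                     snp_source: str = "union",
                     primary_exposure: Optional[str] = None) -> MVMRInput:
    """Assemble a joint MVMR input from per-exposure summary statistics.

    Instruments are selected per exposure (significance filter + optional
    clumping); ``snp_source="union"`` (default) pools them, ``"primary"``
    uses only the primary exposure's instruments.  Every exposure table
    and the outcome must then report each selected SNP; incomplete SNPs
    are dropped (audited on the result's ``extra``).  All effects are
    aligned to the first exposure's effect alleles.
    """
    if len(exposures) < 2:
        raise ConfigurationError("MVMR needs at least 2 exposures")
    config = instrument_config or InstrumentConfig()
    names = list(exposures)
    if primary_exposure is None:
        primary_exposure = names[0]
    if snp_source == "union":
        selected: list[str] = []
        for name in names:
            strong, _, _ = _select_instruments(exposures[name], config, ld)
            selected.extend(s for s in strong.df["snp_id"] if s not in selected)
    elif snp_source == "primary":
        strong, _, _ = _select_instruments(exposures[primary_exposure], config, ld)
        selected = list(strong.df["snp_id"])
    else:
        raise ConfigurationError("snp_source must be 'union' or 'primary'")

    ref = exposures[names[0]]
    ref_sel = ref.subset([s for s in selected if s in set(ref.df["snp_id"])])
    # align every other source onto the reference exposure's effect alleles
    aligned: dict[str, pd.DataFrame] = {names[0]: ref_sel.df.set_index("snp_id")}
    for name in names[1:]:
        h = harmonize_sets(ref_sel, exposures[name], palindrome_policy="keep_as_is")
        aligned[name] = h.to_frame().rename(
            columns={"Gamma_hat": "beta", "sigma_y": "se"}).set_index("snp_id")
    h_out = harmonize_sets(ref_sel, outcome, palindrome_policy="keep_as_is")
    out_df = h_out.to_frame().rename(
        columns={"Gamma_hat": "beta", "sigma_y": "se"}).set_index("snp_id")

    complete = [s for s in ref_sel.df["snp_id"]
                if all(s in aligned[n].index for n in names) and s in out_df.index]
    if len(complete) <= len(names):
        raise InputError(
            f"only {len(complete)} SNPs complete across all sources; "
            f"need more than K={len(names)}")
    X = np.column_stack([aligned[n].loc[complete, "beta"].to_numpy(float)
                         for n in names])
    SX = np.column_stack([aligned[n].loc[complete, "se"].to_numpy(float)
                          for n in names])
    return MVMRInput(snp_ids=list(complete), exposure_betas=X, exposure_ses=SX,
                     outcome_betas=out_df.loc[complete, "beta"].to_numpy(float),
                     outcome_ses=out_df.loc[complete, "se"].to_numpy(float),
                     exposure_names=names,
                     primary_exposure=names.index(primary_exposure),
                     outcome_type=outcome.trait_type)


def run_adjusted_mvmr(exposure: SummaryStatsTable, outcome: SummaryStatsTable,
                      confounders: Mapping[str, SummaryStatsTable],
                      variants: Sequence[Sequence[str]],
                      instrument_config: Optional[InstrumentConfig] = None,
                      ld: Optional[LDMatrix] = None, seed: int = 0,
                      n_boot: int = 500) -> list[dict]:
    """One five-method MVMR bundle per requested confounder subset.

    A collinear subset (e.g. systolic + diastolic + pulse pressure, the
    third being an exact linear function of the first two) does not abort
    the run: its bundle carries ``status="rank_deficient"`` with the
    offending columns and the guidance to drop the derived factor, while
    the remaining subsets are analysed normally.
    """
    if not variants or any(len(v) == 0 for v in variants):
        raise ConfigurationError("each confounder subset must be non-empty")
    bundles = []
    for k, subset in enumerate(variants):
        missing = [c for c in subset if c not in confounders]
        if missing:
            raise ConfigurationError(f"unknown confounders {missing}")
        sources = {exposure.trait_name: exposure}
        sources.update({c: confounders[c] for c in subset})
        bundle = {"confounders": list(subset)}
        try:
            inp = build_mvmr_input(sources, outcome, instrument_config, ld=ld)
            bundle["input"] = inp
            bundle["results"] = all_mvmr_estimators(
                inp, n_boot=n_boot, seed=child_seed(seed, "mvmr", k))
            bundle["status"] = "ok"
        except RankDeficiencyError as err:
            bundle["status"] = "rank_deficient"
            bundle["columns"] = err.columns
            bundle["guidance"] = (
                "drop the derived factor (it is an exact linear combination "
                "of the others) and rerun with the reduced subset")
        bundles.append(bundle)
    return bundles


def run_positive_control(exposures: Mapping[str, SummaryStatsTable],
                         control_outcome: SummaryStatsTable,
                         instrument_config: Optional[InstrumentConfig] = None,
                         ld: Optional[LDMatrix] = None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """IVW of each exposure on a positive-control outcome.

    An exposure passes when its estimate is significant at ``alpha`` in
    the harm-increasing (positive log-OR) direction — the expected
    behaviour of valid instruments against a well-established outcome.
    """
    config = instrument_config or InstrumentConfig()
    rows = []
    for name, table in exposures.items():
        strong, _, _ = _select_instruments(table, config, ld)
        hset = harmonize_sets(strong, control_outcome)
        if len(hset) < 1:
            rows.append({"exposure": name, "status": "underpowered",
                         "passed": False})
            continue
        est = to_odds_scale(ivw(hset, model="fixed"), control_outcome.trait_type)
        d = est.to_dict()
        d.update({"exposure": name, "status": "ok",
                  "passed": bool(est.pvalue < alpha and est.beta > 0)})
        rows.append(d)
    return pd.DataFrame(rows)
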