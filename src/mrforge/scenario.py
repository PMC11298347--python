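"""A packaged synthetic study with the shape of a real MR analysis.

Four glycemic exposures (a diabetes-liability analog plus three
quantitative glycemic traits) are tested against a rare-disease primary
outcome, an even rarer validation outcome, and a common-disease positive
control.  Sample sizes, case fractions and instrument counts mirror the
scale of large public GWAS consortia; the generative truth is a null
causal effect on the primary and validation outcomes and a positive
(harm-increasing) log-odds effect on the control, so a correct pipeline
should find nothing past the Bonferroni bar on the primary outcome while
every positive-control estimate comes out significant and positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from ._rng import child_seed
from .instruments import InstrumentConfig
from .pipeline import bonferroni_threshold, run_positive_control, run_univariable
from .simulate import SimulationConfig, simulate_study

__all__ = ["ScenarioSpec", "EXPOSURE_ROLES", "OUTCOME_ROLES", "run_study"]

#: exposure roles: (instrument count, exposure GWAS sample size)
EXPOSURE_ROLES = {
    "diabetes_liability": (150, 898_130),
    "fasting_glucose": (70, 196_991),
    "fasting_insulin": (38, 196_991),
    "hba1c": (75, 196_991),
}

#: outcome roles: (sample size, case fraction, true log-OR per exposure role)
OUTCOME_ROLES = {
    "primary": (382_944, 967 / 382_944, {r: 0.0 for r in EXPOSURE_ROLES}),
    "validation": (361_194, 127 / 361_194, {r: 0.0 for r in EXPOSURE_ROLES}),
    "control": (340_599, 63_731 / 340_599, {
        "diabetes_liability": math.log(1.12),
        "fasting_glucose": math.log(1.26),
        "fasting_insulin": math.log(1.91),
        "hba1c": math.log(1.44),
    }),
}


@dataclass
class ScenarioSpec:
    """Configuration of the packaged study scenario."""

    seed: int = 0
    alpha: float = 0.05
    n_tests: int = 45          #: Bonferroni family size (0.05/45 ≈ 1.11e-3)
    n_boot: int = 500
    n_sim: int = 1000
    instrument_config: InstrumentConfig = field(default_factory=InstrumentConfig)


def run_study(spec: Optional[ScenarioSpec] = None) -> dict:
    """Run the packaged scenario end to end.

    Returns a dict with:

    * ``summary``: one row per exposure × outcome with the primary (IVW)
      estimate, OR and CI, p-value, and its Bonferroni call;
    * ``results``: the full :class:`UnivariableResult` bundles;
    * ``positive_control``: the control table with pass flags;
    * ``bonferroni_threshold``: the adjusted threshold used.

    Fully reproducible from ``spec.seed``.
    """
    spec = spec or ScenarioSpec()
    threshold = bonferroni_threshold(spec.alpha, spec.n_tests)
    rows = []
    results = {}
    control_exposures = {}
    control_outcome_table = None

    for ename, (J, n_x) in EXPOSURE_ROLES.items():
        for oname, (n_y, cf, thetas) in OUTCOME_ROLES.items():
            pair_seed = child_seed(spec.seed, f"{ename}|{oname}")
            study = simulate_study(
                SimulationConfig(J=J, theta=thetas[ename], n_x=n_x, n_y=n_y,
                                 outcome_type="binary", case_fraction=cf,
                                 seed=pair_seed),
                exposure_name=ename, outcome_name=oname)
            if oname == "control":
                control_exposures[ename] = study.exposure_table
                control_outcome_table = study.outcome_table
                continue
            res = run_univariable(
                study.exposure_table, study.outcome_table,
                instrument_config=spec.instrument_config,
                seed=pair_seed, n_boot=spec.n_boot, n_sim=spec.n_sim)
            results[(ename, oname)] = res
            if res.status == "ok":
                est = res.estimate("ivw_fixed")
                rows.append({
                    "exposure": ename, "outcome": oname, "n_snps": est.n_snps,
                    "beta": est.beta, "se": est.se, "pvalue": est.pvalue,
                    "or": est.or_scale[0], "or_ci_low": est.or_scale[1],
                    "or_ci_high": est.or_scale[2],
                    "bonferroni_significant": bool(est.pvalue < threshold)})
            else:
                rows.append({"exposure": ename, "outcome": oname,
                             "n_snps": 0, "bonferroni_significant": False})

    # positive control: each exposure against its own simulated control
    # outcome (pairwise independent GWAS, as in a two-sample design)
    control_rows = []
    for ename, exposure_table in control_exposures.items():
        pair_seed = child_seed(spec.seed, f"{ename}|control")
        study = simulate_study(
            SimulationConfig(
                J=EXPOSURE_ROLES[ename][0],
                theta=OUTCOME_ROLES["control"][2][ename],
                n_x=EXPOSURE_ROLES[ename][1],
                n_y=OUTCOME_ROLES["control"][0],
                outcome_type="binary",
                case_fraction=OUTCOME_ROLES["control"][1],
                seed=pair_seed),
            exposure_name=ename, outcome_name="control")
        ctrl = run_positive_control(
            {ename: study.exposure_table}, study.outcome_table,
            instrument_config=spec.instrument_config, alpha=spec.alpha)
        control_rows.append(ctrl)

    return {
        "summary": pd.DataFrame(rows),
        "results": results,
        "positive_control": pd.concat(control_rows, ignore_index=True),
        "bonferroni_threshold": threshold,
    }
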