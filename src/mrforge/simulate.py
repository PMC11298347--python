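"""Synthetic GWAS summary statistics with known causal structure.

The generator emulates the data model behind two-sample MR: two
independent GWAS — one of the exposure, one of the outcome — measured on
the same J instruments.  Traits are standardized (variance 1), so the
sampling SE of a per-SNP effect is the closed form
σ = 1/sqrt(2·n·maf·(1−maf)); for a binary outcome analysed on the log-odds
scale the SE is additionally inflated by 1/sqrt(cf·(1−cf)) with cf the
case fraction, an approximation to logistic-regression GWAS standard
errors.

The structural model per SNP j:

    γ̂_j  = γ_j + N(0, σx_j)                       exposure association
    Γ̂_j  = θ·γ_j + α_j + N(0, σy_j)               outcome association

with true effects γ_j ~ N(0, gamma_sd²), causal effect θ, and horizontal
pleiotropy α_j nonzero on a configurable fraction of SNPs, drawn
N(pleio_mu, pleio_sd²) with optional correlation to instrument strength
(``inside_violation_rho``; 0 means the InSIDE condition holds).  Effect
alleles are reported on the exposure-increasing orientation (γ_j ≥ 0), the
convention under which directional pleiotropy μ_α > 0 is a directional
quantity and the Egger intercept estimates it.

Everything is reproducible from a single integer seed via named RNG
streams, so adding a new random quantity never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .exceptions import ConfigurationError, InputError
from .harmonization import HarmonizedSet
from .instruments import LDMatrix, TraitCatalog
from .mvmr import MVMRInput
from .sumstats_io import COLUMNS, SummaryStatsTable

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study",
           "simulate_ld", "simulate_trait_catalog", "simulate_mvmr_study"]

#: non-palindromic allele pairs used for simulated variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification of one synthetic two-sample study.

    Defaults describe a well-powered modern setting: 50 independent
    instruments, exposure and outcome GWAS of 100,000 individuals each,
    per-SNP effects of SD 0.05 trait-SD units (median instrument F in the
    tens), no pleiotropy and no causal effect.
    """

    J: int = 50
    theta: float = 0.0
    maf_range: tuple = (0.05, 0.5)
    gamma_sd: float = 0.05
    n_x: int = 100_000
    n_y: int = 100_000
    outcome_type: str = "quantitative"   #: "quantitative" or "binary"
    case_fraction: float = 0.1           #: cases/total for a binary outcome
    pleio_mu: float = 0.0
    pleio_sd: float = 0.0
    pleio_fraction: float = 0.0
    inside_violation_rho: float = 0.0
    ld_blocks: Optional[tuple] = None    #: (block_size, within_block_rho)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.J < 1:
            raise ConfigurationError("J must be at least 1")
        if not (0 <= self.pleio_fraction <= 1):
            raise ConfigurationError("pleio_fraction must lie in [0, 1]")
        if not (-1 <= self.inside_violation_rho <= 1):
            raise ConfigurationError("inside_violation_rho must lie in [-1, 1]")
        if self.n_x < 2 or self.n_y < 2:
            raise ConfigurationError("sample sizes must be at least 2")
        if self.outcome_type not in ("binary", "quantitative"):
            raise ConfigurationError("outcome_type must be binary or quantitative")
        if not (0 < self.case_fraction < 1):
            raise ConfigurationError("case_fraction must lie in (0, 1)")
        if self.gamma_sd <= 0:
            raise ConfigurationError("gamma_sd must be positive")


@dataclass
class SimulatedStudy:
    """Simulated exposure/outcome tables plus the generative truth."""

    config: SimulationConfig
    exposure_table: SummaryStatsTable
    outcome_table: SummaryStatsTable
    theta: float
    gamma: np.ndarray          #: true per-SNP exposure effects (γ_j ≥ 0)
    alpha: np.ndarray          #: true per-SNP pleiotropic effects
    valid: np.ndarray          #: True where α_j = 0
    ld: Optional[LDMatrix] = None

    def harmonized(self) -> HarmonizedSet:
        """The already-aligned instrument set (both tables share alleles)."""
        e, o = self.exposure_table.df, self.outcome_table.df
        return HarmonizedSet.from_arrays(
            e["beta"].to_numpy(), e["se"].to_numpy(),
            o["beta"].to_numpy(), o["se"].to_numpy(),
            snp_ids=list(e["snp_id"]),
            exposure_name=self.exposure_table.trait_name,
            outcome_name=self.outcome_table.trait_name,
            outcome_type=self.outcome_table.trait_type)


def _table(trait, trait_type, snp_ids, chrom, pos, ea, oa, eaf, beta, se, n):
    z = np.abs(beta / se)
    pvalue = np.maximum(2.0 * stats.norm.sf(z), 5e-324)
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos, "effect_allele": ea,
        "other_allele": oa, "eaf": eaf, "beta": beta, "se": se,
        "pvalue": pvalue, "n": float(n)}, columns=COLUMNS)
    return SummaryStatsTable(trait, trait_type, df)


def simulate_study(config: SimulationConfig,
                   exposure_name: str = "exposure",
                   outcome_name: str = "outcome",
                   snp_prefix: Optional[str] = None) -> SimulatedStudy:
    """Draw one synthetic two-sample study from ``config``.

    Bit-identical under the same config (the seed lives in the config).
    The number of SNPs carrying pleiotropy is exactly
    round(J · pleio_fraction).  Variant identifiers default to a
    seed-derived prefix (distinct seeds give disjoint id spaces); pass
    ``snp_prefix`` to make studies from different seeds share instrument
    identifiers, e.g. to emulate several traits measured on the same SNPs.
    """
    c = config
    J, seed = c.J, c.seed
    maf = stream(seed, "maf").uniform(c.maf_range[0], c.maf_range[1], J)
    gamma = np.abs(stream(seed, "gamma").normal(0.0, c.gamma_sd, J))

    n_pleio = int(round(J * c.pleio_fraction))
    alpha = np.zeros(J)
    valid = np.ones(J, dtype=bool)
    if n_pleio > 0:
        rng_a = stream(seed, "alpha")
        idx = rng_a.choice(J, size=n_pleio, replace=False)
        rho = c.inside_violation_rho
        z_ind = rng_a.normal(size=n_pleio)
        z_g = (gamma[idx] - gamma[idx].mean()) / max(gamma[idx].std(), 1e-12)
        alpha[idx] = c.pleio_mu + c.pleio_sd * (
            rho * z_g + np.sqrt(max(0.0, 1 - rho**2)) * z_ind)
        valid[idx] = False

    sigma_x = 1.0 / np.sqrt(2.0 * c.n_x * maf * (1.0 - maf))
    sigma_y = 1.0 / np.sqrt(2.0 * c.n_y * maf * (1.0 - maf))
    if c.outcome_type == "binary":
        cf = c.case_fraction
        sigma_y = sigma_y / np.sqrt(cf * (1.0 - cf))

    gamma_hat = gamma + stream(seed, "noise_x").normal(0.0, sigma_x)
    Gamma_hat = c.theta * gamma + alpha + stream(seed, "noise_y").normal(0.0, sigma_y)

    rng_al = stream(seed, "alleles")
    pair_idx = rng_al.integers(0, len(_ALLELE_PAIRS), J)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    minor_is_effect = rng_al.random(J) < 0.5
    eaf = np.where(minor_is_effect, maf, 1.0 - maf)

    prefix = f"rs{seed % 1000}" if snp_prefix is None else snp_prefix
    snp_ids = [f"{prefix}{j:05d}" for j in range(J)]
    chrom = [str(1 + j % 22) for j in range(J)]
    pos = np.arange(1, J + 1) * 100_000

    exposure = _table(exposure_name, "quantitative", snp_ids, chrom, pos,
                      ea, oa, eaf, gamma_hat, sigma_x, c.n_x)
    outcome = _table(outcome_name, c.outcome_type, snp_ids, chrom, pos,
                     ea, oa, eaf, Gamma_hat, sigma_y, c.n_y)

    ld = None
    if c.ld_blocks is not None:
        block_size, rho = c.ld_blocks
        ld = simulate_ld(J, block_size, rho, snp_ids=snp_ids)

    return SimulatedStudy(c, exposure, outcome, c.theta, gamma, alpha, valid, ld)


def simulate_ld(J: int, block_size: int, rho: float,
                snp_ids=None) -> LDMatrix:
    """Block-diagonal LD with within-block r² = rho^(2·|i−j|)."""
    if not (0 <= rho < 1):
        raise InputError("rho must lie in [0, 1)")
    if block_size < 1:
        raise InputError("block_size must be at least 1")
    values = np.eye(J)
    for start in range(0, J, block_size):
        stop = min(start + block_size, J)
        idx = np.arange(start, stop)
        dist = np.abs(idx[:, None] - idx[None, :])
        values[np.ix_(idx, idx)] = rho ** (2.0 * dist)
    if snp_ids is None:
        snp_ids = [f"snp_{j}" for j in range(J)]
    return LDMatrix(snp_ids, values)


def simulate_trait_catalog(study: SimulatedStudy, confounder_name: str,
                           hit_fraction: float, hit_p_scale: float = 1e-8,
                           seed: Optional[int] = None) -> tuple[TraitCatalog, list]:
    """Plant confounder-trait associations on a fraction of instruments.

    A ``hit_fraction`` subset of the study's SNPs receives an association
    with ``confounder_name`` at a p-value drawn uniformly in
    (0, ``hit_p_scale``).  Returns (catalog, planted_snp_ids) so screens
    can be checked against the planted truth.
    """
    if not (0 <= hit_fraction <= 1):
        raise InputError("hit_fraction must lie in [0, 1]")
    snp_ids = list(study.exposure_table.df["snp_id"])
    rng = stream(study.config.seed if seed is None else seed, "trait_catalog")
    n_hits = int(round(len(snp_ids) * hit_fraction))
    catalog = TraitCatalog()
    planted: list[str] = []
    if n_hits > 0:
        idx = rng.choice(len(snp_ids), size=n_hits, replace=False)
        for i in sorted(idx):
            p = float(rng.uniform(0.0, 1.0)) * hit_p_scale
            catalog.add(snp_ids[i], confounder_name, max(p, 5e-324))
            planted.append(snp_ids[i])
    return catalog, planted


def simulate_mvmr_study(config: SimulationConfig, K: int,
                        direct_effects, cross_effect_matrix=None,
                        exposure_names=None) -> tuple[MVMRInput, dict]:
    """Simulate K exposures sharing J instruments plus one outcome.

    ``cross_effect_matrix`` is a K×K lower-triangular loading matrix: the
    true per-SNP effect vector for the exposures is L @ z_j with
    independent z_j ~ N(0, gamma_sd²) per exposure, so off-diagonal
    entries induce genetically correlated exposures (identity by default).
    The outcome is built from the specified per-exposure direct effects.

    Returns (MVMRInput, truth) with the true effect matrix and direct
    effects in ``truth``.
    """
    c = config
    direct_effects = np.asarray(direct_effects, float)
    if direct_effects.shape != (K,):
        raise InputError(f"direct_effects must have length K={K}")
    if cross_effect_matrix is None:
        L = np.eye(K)
    else:
        L = np.asarray(cross_effect_matrix, float)
        if L.shape != (K, K):
            raise InputError("cross_effect_matrix must be K×K")
        if not np.allclose(L, np.tril(L)):
            raise InputError("cross_effect_matrix must be lower triangular")
    J, seed = c.J, c.seed
    maf = stream(seed, "maf").uniform(c.maf_range[0], c.maf_range[1], J)
    z = stream(seed, "mvmr_gamma").normal(0.0, c.gamma_sd, size=(J, K))
    gamma_true = z @ L.T                                   # J×K true effects

    sigma_x = 1.0 / np.sqrt(2.0 * c.n_x * maf * (1.0 - maf))
    sigma_y = 1.0 / np.sqrt(2.0 * c.n_y * maf * (1.0 - maf))
    if c.outcome_type == "binary":
        sigma_y = sigma_y / np.sqrt(c.case_fraction * (1.0 - c.case_fraction))

    exposure_ses = np.tile(sigma_x[:, None], (1, K))
    gamma_hat = gamma_true + stream(seed, "mvmr_noise_x").normal(
        0.0, 1.0, size=(J, K)) * exposure_ses
    Gamma_true = gamma_true @ direct_effects
    Gamma_hat = Gamma_true + stream(seed, "mvmr_noise_y").normal(0.0, sigma_y)

    if exposure_names is None:
        exposure_names = [f"exposure_{k}" for k in range(K)]
    snp_ids = [f"rs{seed % 1000}{j:05d}" for j in range(J)]
    inp = MVMRInput(snp_ids=snp_ids, exposure_betas=gamma_hat,
                    exposure_ses=exposure_ses, outcome_betas=Gamma_hat,
                    outcome_ses=sigma_y, exposure_names=list(exposure_names),
                    outcome_type=c.outcome_type)
    truth = {"direct_effects": direct_effects, "gamma_true": gamma_true,
             "loadings": L}
    return inp, truth
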