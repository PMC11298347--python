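import numpy as np
import pandas as pd
import pytest

from mrforge.harmonization import HarmonizedSet
from mrforge.sumstats_io import COLUMNS, SummaryStatsTable


def make_table(trait="trait", trait_type="quantitative", **cols) -> SummaryStatsTable:
    """Build a SummaryStatsTable from keyword columns with sane defaults."""
    n = max(len(v) for v in cols.values())
    df = pd.DataFrame(index=range(n))
    defaults = {
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": ["1"] * n,
        "pos": np.arange(1, n + 1) * 1000,
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "eaf": [0.3] * n,
        "beta": [0.1] * n,
        "se": [0.01] * n,
        "pvalue": [1e-10] * n,
        "n": [100000.0] * n,
    }
    for c in COLUMNS:
        df[c] = cols.get(c, defaults[c])
    return SummaryStatsTable(trait, trait_type, df)


def ratio_set(betas, ses, outcome_type="quantitative") -> HarmonizedSet:
    """Harmonized set whose Wald ratios are exactly ``betas`` with first-order
    ratio SEs ``ses`` (gamma fixed at 1, tiny exposure noise)."""
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    return HarmonizedSet.from_arrays(
        gamma_hat=np.ones_like(betas), sigma_x=np.full_like(betas, 1e-12),
        Gamma_hat=betas, sigma_y=ses, outcome_type=outcome_type)


@pytest.fixture
def toy_tables(tmp_path):
    """A 3-SNP exposure/outcome pair written to disk as TSV."""
    exposure = make_table("exp", beta=[0.10, -0.05, 0.20],
                          pvalue=[1e-10, 1e-9, 1e-12])
    outcome = make_table("out", "binary", beta=[0.02, -0.01, 0.05],
                         se=[0.02, 0.02, 0.02], pvalue=[0.3, 0.6, 0.01])
    return exposure, outcome


@pytest.fixture
def rng():
    return np.random.default_rng(20240722)
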