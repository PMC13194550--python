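import numpy as np
import pandas as pd
import pytest

from mrtaxa import HarmonizedSet, ScenarioConfig, SummaryStatsTable, simulate_study
from mrtaxa.gwas_io import CANONICAL_COLUMNS


def make_table(rows, trait_label="trait", trait_type="quantitative",
               n_cases=None, n_controls=None):
    """Build a SummaryStatsTable from a list of row dicts (canonical fields)."""
    df = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = {"eaf": 0.3, "n": 10_000}.get(col, None)
    return SummaryStatsTable(trait_label=trait_label, trait_type=trait_type,
                             records=df[CANONICAL_COLUMNS],
                             n_cases=n_cases, n_controls=n_controls)


def random_harmonized(rng, n_snp=15, beta=0.2, se_gamma_scale=0.01,
                      se_Gamma_scale=0.02):
    """Small harmonized set with effects drawn around a linear truth."""
    gamma = rng.normal(0.15, 0.05, n_snp) * rng.choice([-1, 1], n_snp)
    se_g = np.full(n_snp, se_gamma_scale) * rng.uniform(0.5, 1.5, n_snp)
    se_G = np.full(n_snp, se_Gamma_scale) * rng.uniform(0.5, 1.5, n_snp)
    gamma_hat = gamma + rng.normal(0, se_g)
    Gamma_hat = beta * gamma + rng.normal(0, se_G)
    return HarmonizedSet.from_arrays(gamma_hat, se_g, Gamma_hat, se_G)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def causal_harmonized():
    """Harmonized 20-instrument set from the causal synthetic scenario."""
    from mrtaxa import harmonize, select_instruments
    exp, out, _ = simulate_study(ScenarioConfig(n_snp=20, beta_true=-0.3, seed=11))
    return harmonize(select_instruments(exp), out)
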