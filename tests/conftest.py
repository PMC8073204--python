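import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mirpair.synthetic import (
    CohortDesign,
    EffectSpec,
    SimulationParams,
    simulate_study,
)


@pytest.fixture(scope="session")
def two_group_design():
    return CohortDesign(groups=("CASE", "CTRL"), n_per_group=(6, 6), seed=11)


@pytest.fixture(scope="session")
def small_study(two_group_design):
    """A small two-group study with one planted effect per layer."""
    effects = [
        EffectSpec("hsa-miR-1-3p", "ct_mirna", "CASE", 1.5),
        EffectSpec("ANXA2", "ct_mrna", "CASE", -1.0),
        EffectSpec("mir-x", "counts", "CASE", 3.0, baseline=10.0),
        EffectSpec("prot-x", "protein", "CASE", -2.0),
    ]
    params = SimulationParams(n_background_counts=40, n_background_proteins=30)
    return simulate_study(two_group_design, effects, params=params, n_decoy_links=5)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_de_table(rows):
    """Helper: DE table from (feature, log2_fc, p, p_adjusted) tuples."""
    df = pd.DataFrame(rows, columns=["feature", "log2_fc", "p", "p_adjusted"])
    df["direction"] = np.where(df["log2_fc"] > 0, "up", "down")
    return df
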