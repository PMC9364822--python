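import numpy as np
import pandas as pd
import pytest

from fsamnps import NutrientProfile, SimConfig, default_bands, generate_cohort, generate_composition


@pytest.fixture(scope="session")
def bands():
    return default_bands()


@pytest.fixture
def worked_profile():
    """General food used in the hand-evaluated scoring example."""
    return NutrientProfile("worked", energy=1500, sugars=20, satfat=5,
                           sodium=500, fiber=2, protein=7, fvln_pct=50)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by pipeline-level tests."""
    config = SimConfig(seed=20260923, n_participants=400, n_clusters=25)
    composition = generate_composition(config)
    return generate_cohort(config, composition)


@pytest.fixture(scope="session")
def toy_regression():
    """Ten-row, two-cluster dataset for brute-force sandwich checks."""
    rng = np.random.default_rng(42)
    x = rng.normal(size=10)
    y = 1.5 + 2.0 * x + rng.normal(size=10)
    return pd.DataFrame({
        "y": y, "x": x,
        "cluster": np.repeat(["a", "b"], 5),
    })
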