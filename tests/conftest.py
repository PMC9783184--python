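import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from adipostage import FeatureMatrix
from adipostage.simulate import SimulationConfig, simulate_expression, simulate_lipidomics

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_lipid_matrix() -> FeatureMatrix:
    """Tiny hand-built species table: 2 groups x 3 samples."""
    values = pd.DataFrame(
        {
            "A1": [3.0, 7.0, 10.0, 2.0],
            "A2": [4.0, 6.0, 11.0, 2.5],
            "B1": [1.0, 2.0, 30.0, 2.0],
            "B2": [1.5, 2.5, 28.0, 2.2],
        },
        index=["TG(16:0/16:1/18:3)", "TG(20:1/18:1/18:3)", "PC(34:2e)", "SM(d34:1)"],
    )
    samples = pd.DataFrame(
        {"group": ["A", "A", "B", "B"], "batch": ["x"] * 4},
        index=values.columns,
    )
    return FeatureMatrix(values, samples)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def expression_cohort(default_config):
    return simulate_expression(default_config)


@pytest.fixture(scope="session")
def lipid_cohort(default_config):
    return simulate_lipidomics(default_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
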