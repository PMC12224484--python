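import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from connclass.cohort import CohortConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A 20-node, 30-structural-node configuration for fast unit tests."""
    return CohortConfig(
        n_subjects=400,
        seed=3,
        functional_nodes=20,
        subnetwork_sizes=(4, 4, 4, 4, 2, 2),
        structural_nodes=30,
        ts_length=120,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def big_cohort():
    """A 10^4-subject cohort at default parameters for calibration checks."""
    config = CohortConfig(n_subjects=10_000, seed=11)
    return config, generate_cohort(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
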