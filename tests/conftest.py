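import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from transferpep import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    """The theoretical model at its published parameters, n = 10."""
    return SimulationConfig(n_group_correct=10)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One seeded dataset at full size, shared by read-only tests."""
    return simulate_dataset(default_config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
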