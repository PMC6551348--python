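import numpy as np
import pytest

from normdev import SimulationConfig, scaled_simulation_config, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced cohort preserving the default design's structure."""
    return scaled_simulation_config(n_td=60, n_asd=60, n_vertices=60,
                                    n_regions=12, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def gp_training_data():
    """Linear-plus-noise age/sex data for GP unit tests."""
    r = np.random.default_rng(3)
    n = 80
    age = r.uniform(6.0, 31.0, n)
    sex = r.integers(0, 2, n).astype(float)
    X = np.column_stack([age, sex])
    y = 3.1 - 0.02 * age + 0.04 * sex + r.normal(0.0, 0.15, n)
    return X, y
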