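import numpy as np
import pytest

from climvuln import SimConfig, generate


@pytest.fixture(scope="session")
def sim_small():
    """One small but complete synthetic data set shared across tests."""
    cfg = SimConfig(n_pops=6, n_ind_per_pop=8, n_neutral=300, n_adaptive=4,
                    grid_shape=(24, 24), seed=11, env_effect=2.5,
                    missing_rate=0.05)
    return generate(cfg)


@pytest.fixture(scope="session")
def sim_single_region():
    """Single-stratum simulation (no second region) for calibration checks."""
    cfg = SimConfig(n_pops=8, n_ind_per_pop=10, n_neutral=500, n_adaptive=0,
                    grid_shape=(24, 24), seed=17, n_second_region_pops=0,
                    missing_rate=0.0, inject_relatives=False)
    return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
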