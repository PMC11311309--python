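import numpy as np
import pytest

from freshshelf import GrowthParams, default_trial_config, simulate_trial

# Published modified-Gompertz fits for the three treatment arms of the
# 4 C / 10 d fresh-cut radish trial; reused across the suite.
TABLE_GOMPERTZ = {
    "CK": GrowthParams(4.691, 6.912, 0.431, 0.087),
    "NaClO": GrowthParams(3.790, 5.701, 0.752, 0.240),
    "PDT": GrowthParams(2.258, 7.732, 0.758, 0.623),
}


@pytest.fixture(scope="session")
def gompertz_ck():
    return TABLE_GOMPERTZ["CK"]


@pytest.fixture(scope="session")
def gompertz_pdt():
    return TABLE_GOMPERTZ["PDT"]


@pytest.fixture(scope="session")
def sigma0_config():
    """Default trial configuration with all replicate noise switched off."""
    cfg = default_trial_config(seed=1)
    cfg.noise_sd = {a: 0.0 for a in cfg.noise_sd}
    return cfg


@pytest.fixture(scope="session")
def sigma0_dataset(sigma0_config):
    return simulate_trial(sigma0_config)


@pytest.fixture(scope="session")
def noisy_dataset():
    return simulate_trial(default_trial_config(seed=42))


def random_growth_params(rng: np.random.Generator) -> GrowthParams:
    """A random valid parameter set for property tests."""
    n0 = rng.uniform(1.0, 5.0)
    span = rng.uniform(1.0, 5.0)
    mu = rng.uniform(0.1, 2.0)
    lag = rng.uniform(0.0, 3.0)
    return GrowthParams(n0, n0 + span, mu, lag)
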