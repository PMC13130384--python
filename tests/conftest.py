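import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("default")

import r2dt


@pytest.fixture(scope="session")
def grid():
    return r2dt.default_grid()


@pytest.fixture(scope="session")
def prior():
    return r2dt.default_prior()


@pytest.fixture(scope="session")
def rd_utility():
    """Reference-dependent utility stack of the primary design."""
    return r2dt.r2dt_utility()


@pytest.fixture(scope="session")
def linear_utility():
    """Linear-marginal (patient-outcome) utility with the same corner weights."""
    return r2dt.efftoxu_utility_stack()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


FAST_MCMC = {"n_draws": 800, "warmup": 300, "thin": 2, "n_chains": 8}
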