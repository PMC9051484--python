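import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from twinage.synthetic import simulate_wide, true_common_pathway, true_univariate


@pytest.fixture(scope="session")
def ae_true():
    return true_univariate("AE", a=0.8, e=0.6)


@pytest.fixture(scope="session")
def ae_wide_large(ae_true):
    """AE twin data big enough that moments are within ~1% of truth."""
    return simulate_wide(ae_true, 5000, 5000, seed=11)


@pytest.fixture(scope="session")
def ae_wide_small(ae_true):
    return simulate_wide(ae_true, 300, 300, seed=12)


@pytest.fixture(scope="session")
def cp_true():
    return true_common_pathway()


@pytest.fixture(scope="session")
def cp_wide(cp_true):
    return simulate_wide(cp_true, 1000, 1000, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(2023)
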