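import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from privkmer.he import CryptoParams, create_context

settings.register_profile(
    "suite",
    max_examples=20,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_params():
    return CryptoParams.tiny_profile()


@pytest.fixture(scope="session")
def clear_ctx(tiny_params):
    return create_context(tiny_params, backend="clear")


@pytest.fixture(scope="session")
def clear_keys(clear_ctx):
    return clear_ctx.keygen(7)


@pytest.fixture(scope="session")
def bfv_ctx(tiny_params):
    return create_context(tiny_params, backend="bfv", seed=13)


@pytest.fixture(scope="session")
def bfv_keys(bfv_ctx):
    return bfv_ctx.keygen(13)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
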