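import numpy as np
import pytest
from hypothesis import settings

from netfunc.reference import n5_model

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")
from netfunc.dynamics import build_rate_function, equilibrate


@pytest.fixture(scope="session")
def n5():
    """The N5 reference topology and printed parameters."""
    return n5_model()


@pytest.fixture(scope="session")
def n5_rate(n5):
    topology, params = n5
    return build_rate_function(topology, params)


@pytest.fixture(scope="session")
def n5_basal(n5_rate):
    """Equilibrated basal resting state of N5 (also warms the jit cache)."""
    converged, x = equilibrate(n5_rate)
    assert converged
    return x


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
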