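import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dgasim.dga_engine import Smoothing
from dgasim.promoter_models import TwoStateParams, build_two_state


@pytest.fixture(scope="session")
def paper_params():
    """The benchmark telegraph parameters: kon=0.5, koff=1, r=10, gamma=1."""
    return TwoStateParams(kon_r=0.5, koff_r=1.0, r=10.0, gamma=1.0)


@pytest.fixture(scope="session")
def two_state_system(paper_params):
    return build_two_state(paper_params)


@pytest.fixture(scope="session")
def default_smoothing():
    return Smoothing.from_inverse(200.0, 20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


class QueuedRng:
    """Deterministic stand-in for a Generator: returns queued uniforms."""

    def __init__(self, values):
        self._values = list(values)

    def random(self):
        return self._values.pop(0)


@pytest.fixture()
def queued_rng():
    return QueuedRng
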