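import numpy as np
import pytest

from cicrsim import GridSpec, ModelParams, improved_params
from cicrsim.fixtures import tiny_grid


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def iparams(params):
    return params.internal()


@pytest.fixture
def improved():
    return improved_params()


@pytest.fixture
def grid1d():
    return tiny_grid(ndim=1, duration=1.0)


@pytest.fixture
def grid2d():
    return tiny_grid(ndim=2, duration=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


class StubRng:
    """Deterministic stand-in for a Generator: returns a constant uniform."""

    def __init__(self, value: float):
        self.value = value

    def random(self, n):
        return np.full(n, self.value)


@pytest.fixture
def rng_zero():
    return StubRng(0.0)


@pytest.fixture
def rng_one():
    return StubRng(1.0 - 1e-12)
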