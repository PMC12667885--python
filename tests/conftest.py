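import numpy as np
import pytest

from stabsel.params import ModelParams
from stabsel.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(171)


@pytest.fixture
def base_params():
    """A mid-range architecture well inside the SHOC regime."""
    return ModelParams(ne=1000.0, u=0.01, vm=1e-3, vs=1.0)


@pytest.fixture
def small_cfg():
    """A cheap simulation config for unit-level runs."""
    return SimConfig(n=100, u=0.01, vm=1e-3, vs=1.0, n_samples=10, seed=11)
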