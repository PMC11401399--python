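import numpy as np
import pytest

from gridabm.dynamics import CycleParams, MotionParams, SimulationState
from gridabm.lattice import LatticeDomain
from gridabm.radiation import RadiosensitivityParams


@pytest.fixture
def dom():
    return LatticeDomain()


@pytest.fixture
def motion():
    return MotionParams()


@pytest.fixture
def cycle():
    return CycleParams()


@pytest.fixture
def radio():
    return RadiosensitivityParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def state():
    st = SimulationState()
    st.seed_kernel(99)
    return st
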