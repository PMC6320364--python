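import numpy as np
import pytest

from pathtimes import (
    IntervalSpec,
    Linear,
    SimConfig,
    Trajectory,
    quartic_from_barrier,
)


@pytest.fixture(scope="session")
def paper_quartic():
    """Bistable asymmetric quartic at the printed simulation parameters
    (barrier 5 kBT, asymmetry 2 kBT, well separation 1 µm)."""
    return quartic_from_barrier(5.0, 2.0, 1.0)


@pytest.fixture(scope="session")
def mild_quartic():
    """Fast-relaxing bistable quartic used for equilibrium event statistics."""
    return quartic_from_barrier(2.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def channel_interval():
    """Measurement interval of the microchannel exit experiments (L = 3.7 µm)."""
    return (-1.85, 1.85)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_traj(x, dt=1.0, fext=None):
    x = np.asarray(x, dtype=float)
    return Trajectory(t=np.arange(x.size) * dt, x=x, fext=fext)
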