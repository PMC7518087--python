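import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tumorca.state import Geometry, LatticeState

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(positions, tau, age=None, L=20, t=0.0) -> LatticeState:
    """Build a small LatticeState from explicit (row, col) positions."""
    pos = np.asarray(positions, dtype=np.int64).reshape(-1, 2)
    n = len(pos)
    tau = np.full(n, float(tau)) if np.isscalar(tau) else np.asarray(tau, float)
    age = np.zeros(n) if age is None else (
        np.full(n, float(age)) if np.isscalar(age) else np.asarray(age, float)
    )
    return LatticeState(Geometry(side_sites=L), pos[:, 0], pos[:, 1], tau, age, t=t)


@pytest.fixture
def lone_cell_state():
    """One ripe cell in the middle of an empty 20x20 grid."""
    return make_state([(10, 10)], tau=24.0, age=24.0)


@pytest.fixture
def enclosed_state():
    """A full 5x5 block: the center cell has no free 2-Moore site."""
    pos = [(r, c) for r in range(8, 13) for c in range(8, 13)]
    return make_state(pos, tau=24.0, age=24.0)
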