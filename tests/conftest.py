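"""Shared fixtures.

Expensive objects (default 100x50 grids, excluded-volume kernels, solved
coexistence points) are session-scoped so the suite builds each of them
once.
"""

import numpy as np
import pytest

from hardnem.angular import build_grid
from hardnem.geometry import ProlateSpheroid
from hardnem.mixture_bmcsl import MixtureSpec, MixtureSystem
from hardnem.pure_onsager import PureSystem


@pytest.fixture(scope="session")
def grid_default():
    return build_grid(100, 50)


@pytest.fixture(scope="session")
def grid_small():
    return build_grid(24, 16)


@pytest.fixture(scope="session")
def sp39():
    """c/a = 3 benchmark spheroid (a = 3 nm, c = 9 nm)."""
    return ProlateSpheroid(3.0, 9.0)


@pytest.fixture(scope="session")
def sphere_unit():
    return ProlateSpheroid(1.0, 1.0)


@pytest.fixture(scope="session")
def c9_rigorous_z3(grid_default):
    return PureSystem(ProlateSpheroid(3.0, 9.0), "rigorous", 3.0, grid=grid_default)


@pytest.fixture(scope="session")
def c9_rigorous_z3_coex(c9_rigorous_z3):
    return c9_rigorous_z3.coexistence()


@pytest.fixture(scope="session")
def c15_rigorous_z3(grid_default):
    """Long-particle benchmark (a = 3, c = 15 nm) with the rigorous
    excluded volume and z = 3."""
    return PureSystem(ProlateSpheroid(3.0, 15.0), "rigorous", 3.0, grid=grid_default)


@pytest.fixture(scope="session")
def mix_12_9(grid_default):
    """Binary benchmark mixture: A = (3, 12) nm, B = (3, 9) nm, z = 3."""
    spec = MixtureSpec(ProlateSpheroid(3.0, 12.0), ProlateSpheroid(3.0, 9.0))
    return MixtureSystem(spec, 3.0, grid=grid_default)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
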