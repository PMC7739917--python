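import numpy as np
import pytest

from vasclbm import lattice as lb
from vasclbm import geometry


@pytest.fixture(scope="session")
def lat():
    return lb.build_d3q19()


@pytest.fixture(scope="session")
def tube():
    """Small straight tube with inlet and outlet patches."""
    return geometry.make_tube(5, 20)


@pytest.fixture(scope="session")
def one_to_three():
    """The 1:3 arterial/venous fixture pair."""
    return geometry.make_one_to_n_domain(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def closed_box(n=8):
    """All-wall cubic cavity of n^3 fluid sites (solid shell)."""
    sc = np.zeros((n + 2, n + 2, n + 2), dtype=np.uint8)
    sc[1:-1, 1:-1, 1:-1] = geometry.FLUID
    dom = geometry.VoxelDomain(site_class=sc, dx=1.0)
    from vasclbm.geometry import _mark_wall_adjacent

    _mark_wall_adjacent(dom.site_class)
    return dom
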