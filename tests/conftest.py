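import numpy as np
import pytest

from wlcbrush.chain import ChainParams, init_conformation
from wlcbrush.field import FieldGrid, build_orientation_grid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    """Standard-regime chain (L/a = 30) at reduced bond count."""
    return ChainParams(N=30.0, Nm=20)


@pytest.fixture
def straight(params):
    return init_conformation(params)


@pytest.fixture
def ogrid():
    return build_orientation_grid(8, 8)


@pytest.fixture
def zero_field(params, ogrid):
    return FieldGrid.zeros(40, 1.2 * params.contour_length, ogrid)


def random_conformation(params, rng, graft=(0.0, 0.0, 0.0)):
    """Uniformly random unit bonds (not Boltzmann; geometry tests only)."""
    from wlcbrush.chain import Conformation, rebuild_positions
    u = rng.normal(size=(params.Nm, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    g = np.asarray(graft, dtype=float)
    return Conformation(g, rebuild_positions(u, g, params.bond_length), u,
                        params.bond_length)
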