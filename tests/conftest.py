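import numpy as np
import pytest

from epivertex.mechanics import ElasticCoeffs, ReferenceState
from epivertex.mesh import make_hex_patch, make_regular_hexagon


@pytest.fixture
def hexagon():
    return make_regular_hexagon(1.0)


@pytest.fixture
def patch7():
    return make_hex_patch(7)


@pytest.fixture
def patch32():
    return make_hex_patch(32)


@pytest.fixture
def ref():
    return ReferenceState()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def uniform_coeffs(mesh, eta=0.9, mu=0.1, sigma=1.0, phi=1.0):
    return ElasticCoeffs.uniform(mesh.n_cells, eta, mu, sigma, phi)
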