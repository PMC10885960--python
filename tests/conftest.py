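import numpy as np
import pytest

from xlct.forward import OpticalTissue
from xlct.mesh import Mesh, build_cylinder_mesh


@pytest.fixture(scope="session")
def tissue():
    """The phantom medium: mu_a = 0.02 cm^-1, mu_s' = 10 cm^-1."""
    return OpticalTissue()


@pytest.fixture(scope="session")
def small_mesh():
    """A coarse cylinder small enough for dense linear algebra."""
    return build_cylinder_mesh(1.0, 1.0, 0.5)


@pytest.fixture(scope="session")
def phantom_mesh():
    """The coarse reconstruction mesh of the two-tube phantom."""
    return build_cylinder_mesh(1.5, 2.6, 0.28)


@pytest.fixture()
def unit_tet():
    """A single tetrahedron scaled to unit volume."""
    # right tet with legs a: volume a^3/6 = 1  =>  a = 6^(1/3)
    a = 6.0 ** (1.0 / 3.0)
    coords = np.array(
        [[0, 0, 0], [a, 0, 0], [0, a, 0], [0, 0, a]], dtype=float
    )
    return Mesh(coords, np.array([[0, 1, 2, 3]]))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240126)
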