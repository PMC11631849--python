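import numpy as np
import pytest

from lase.mesh import AtrialMesh
from lase.synthetic import SimulationSpec, make_atrium_mesh


@pytest.fixture
def tetrahedron() -> AtrialMesh:
    """Smallest closed triangulation, consistently wound (outward)."""
    v = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return AtrialMesh(v, f).validate()


@pytest.fixture(scope="session")
def small_atrium() -> AtrialMesh:
    """A ~650-vertex bumpy-ellipsoid shell shared across tests."""
    return make_atrium_mesh(SimulationSpec(n_mesh_vertices=650, n_points=0, seed=7))


@pytest.fixture(scope="session")
def medium_atrium() -> AtrialMesh:
    return make_atrium_mesh(SimulationSpec(n_mesh_vertices=2000, n_points=0, seed=11))
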