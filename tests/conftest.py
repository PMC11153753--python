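import numpy as np
import pytest
import trimesh

from fetalfold.mesh import TriMesh

# edge-length-1 regular tetrahedron (closed, positively oriented)
TETRA_VERTS = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.5, np.sqrt(3) / 2, 0.0],
        [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3],
    ]
)
TETRA_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])


@pytest.fixture(scope="session")
def tetra() -> TriMesh:
    return TriMesh(TETRA_VERTS, TETRA_FACES, closed=True)


def make_icosphere(radius: float = 10.0, subdivisions: int = 4) -> TriMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), closed=True)


@pytest.fixture(scope="session")
def icosphere4() -> TriMesh:
    return make_icosphere(10.0, 4)


@pytest.fixture(scope="session")
def cube() -> TriMesh:
    tm = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), closed=True)


@pytest.fixture(scope="session")
def template29():
    """29 GW synthetic template surface + basin graph (expensive; shared)."""
    from fetalfold.synthetic import synth_template

    mesh, graph, coeffs = synth_template()
    return mesh, graph, coeffs
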