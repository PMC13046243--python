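import numpy as np
import pytest
import trimesh

from neolaminar.equivolume import CorticalRibbon, SurfaceMesh


def icosphere_mesh(subdivisions: int, radius: float = 1.0) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices, dtype=float),
                       np.asarray(ico.faces, dtype=np.int64))


@pytest.fixture(scope="session")
def unit_icosphere4() -> SurfaceMesh:
    return icosphere_mesh(4)


@pytest.fixture(scope="session")
def sphere_ribbon() -> CorticalRibbon:
    """Concentric-sphere ribbon, white radius 2, pial radius 3."""
    white = icosphere_mesh(3, radius=2.0)
    pial = SurfaceMesh(white.vertices * 1.5, white.triangles)
    return CorticalRibbon(pial=pial, white=white)


@pytest.fixture(scope="session")
def flat_ribbon() -> CorticalRibbon:
    """Parallel flat square sheets 2 mm apart (equal vertex areas)."""
    n = 8
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris.append([a, a + 1, a + n])
            tris.append([a + 1, a + n + 1, a + n])
    tris = np.asarray(tris, dtype=np.int64)
    white = SurfaceMesh(verts, tris)
    pial_verts = verts.copy()
    pial_verts[:, 2] = 2.0
    return CorticalRibbon(pial=SurfaceMesh(pial_verts, tris), white=white)
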