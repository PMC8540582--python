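"""Shared fixtures: small meshes and slab scenes built programmatically."""

import numpy as np
import pytest

from orthosim.fixtures import FixtureSpec, make_slab_scene
from orthosim.geometry import SurfaceMesh, TetMesh

_BOX_FACES = np.array(
    [
        [0, 2, 1], [1, 2, 3], [4, 5, 6], [5, 7, 6],
        [0, 1, 4], [1, 5, 4], [2, 6, 3], [3, 6, 7],
        [0, 4, 2], [2, 4, 6], [1, 3, 5], [3, 7, 5],
    ]
)


def box_surface(lo, hi) -> SurfaceMesh:
    """Closed, outward-oriented axis-aligned box (12 triangles)."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    v = np.array(
        [
            [lo[0], lo[1], lo[2]], [hi[0], lo[1], lo[2]],
            [lo[0], hi[1], lo[2]], [hi[0], hi[1], lo[2]],
            [lo[0], lo[1], hi[2]], [hi[0], lo[1], hi[2]],
            [lo[0], hi[1], hi[2]], [hi[0], hi[1], hi[2]],
        ]
    )
    return SurfaceMesh(v, _BOX_FACES.copy())


def icosphere(radius=10.0, subdivisions=2, scale=(1.0, 1.0, 1.0)) -> SurfaceMesh:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices) * np.asarray(scale, float),
                       np.asarray(ico.faces))


def random_tet_mesh(seed=0, n_points=22, extent=10.0) -> TetMesh:
    """Delaunay mesh of random points (roughly 50-100 tets), slivers removed."""
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, extent, (n_points, 3))
    tri = Delaunay(pts)
    tets = tri.simplices
    x = pts[tets]
    vols = np.abs(np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0)
    tets = tets[vols > 1e-3 * extent**3 / len(tets)]
    used = np.unique(tets)
    remap = np.full(len(pts), -1)
    remap[used] = np.arange(len(used))
    return TetMesh(pts[used], remap[tets])


@pytest.fixture(scope="session")
def unit_tet():
    X = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    return TetMesh(X, [[0, 1, 2, 3]])


@pytest.fixture(scope="session")
def cut_slab_scene():
    """Standard two-fragment scene: 60x20x20 mm slab, 5 mm cells, one
    embedded bone block cut by the mid-plane x = 30."""
    spec = FixtureSpec(
        slab_dimensions=[60.0, 20.0, 20.0],
        grid_resolution=(12, 4, 4),
        bone_blocks=[([15.0, 5.0, 5.0], [45.0, 15.0, 10.0])],
        cut_planes=[[([30.0, 10.0, 7.5], [1.0, 0.0, 0.0])]],
        fixed_region="zmax",
    )
    return make_slab_scene(spec)
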