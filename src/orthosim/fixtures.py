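"""Synthetic slab-and-block scenes.

Real planning scenes (skull, maxilla/mandible fragments, facial tissue)
cannot be redistributed, so every part of the pipeline is exercised on
structured analogues: a rectangular soft-tissue slab meshed with a
conforming 5-tets-per-hex decomposition, with axis-aligned "bone" blocks
embedded as voids whose boundary triangles are vertex-identical with the
tissue mesh -- the same matched tissue--bone interface the clinical
pipeline obtains from a Boolean difference.  Cut planes split a block
into fragments and induce the face groups that drive coupling
assignment, exactly as an osteotomy does.

Optional seeded jitter perturbs interior nodes (never interface or outer
boundary nodes) to test irregular meshes without breaking interface
conformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coupling import assign_face_groups, build_coupling, lbs_weight_field
from .fem import Material
from .geometry import MeshValidationError, SurfaceMesh, TetMesh, Transform
from .rigid import RigidFragment, TransformTrajectory, make_trajectory
from .solver import Scene

__all__ = ["FixtureSpec", "make_slab_scene", "make_advance_plan"]


# 5-tet decomposition of a hex; corner c = ix + 2*iy + 4*iz.
_TETS_EVEN = np.array(
    [[0, 1, 2, 4], [1, 2, 3, 7], [1, 4, 5, 7], [2, 4, 6, 7], [1, 2, 4, 7]]
)
_FLIP_X = np.array([1, 0, 3, 2, 5, 4, 7, 6])
_TETS_ODD = _FLIP_X[_TETS_EVEN]


@dataclass
class FixtureSpec:
    """Geometry of a slab-and-block scene.

    ``bone_blocks`` are (lo, hi) corner pairs in mm; their bounds are
    snapped to the structured grid so the tissue--bone interface is
    vertex-identical by construction.  ``cut_planes[b]`` lists
    (point, normal) planes cutting block b; axis-aligned grid-snapped
    planes yield closed (capped) fragment surfaces.
    """

    slab_dimensions: np.ndarray = field(default_factory=lambda: np.array([60.0, 20.0, 20.0]))
    grid_resolution: tuple[int, int, int] = (12, 4, 4)
    bone_blocks: list[tuple] = field(default_factory=list)
    cut_planes: list[list[tuple]] = field(default_factory=list)
    fixed_region: str = "none"  # one of none, xmin, xmax, ymin, ymax, zmin, zmax
    seed: int = 0
    jitter_fraction: float = 0.0  # <= 0.2 of the cell size, interior nodes only
    lbs_ramp_mm: float = 10.0
    material: Material = field(default_factory=Material)

    def __post_init__(self) -> None:
        self.slab_dimensions = np.asarray(self.slab_dimensions, float).reshape(3)
        if any(r < 2 for r in self.grid_resolution):
            raise ValueError("grid_resolution must be >= 2 cells per axis")
        if not 0.0 <= self.jitter_fraction <= 0.2:
            raise ValueError("jitter_fraction must lie in [0, 0.2]")
        if self.fixed_region not in {"none", "xmin", "xmax", "ymin", "ymax", "zmin", "zmax"}:
            raise ValueError(f"unknown fixed_region {self.fixed_region!r}")
        while len(self.cut_planes) < len(self.bone_blocks):
            self.cut_planes.append([])


def _snap_block(lo, hi, axes) -> tuple[np.ndarray, np.ndarray]:
    """Snap block corners to grid node indices; block must stay strictly
    inside the slab and span at least one cell per axis."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    ilo = np.empty(3, int)
    ihi = np.empty(3, int)
    for k in range(3):
        ilo[k] = int(np.argmin(np.abs(axes[k] - lo[k])))
        ihi[k] = int(np.argmin(np.abs(axes[k] - hi[k])))
        n = len(axes[k]) - 1
        if not 1 <= ilo[k] < ihi[k] <= n - 1:
            raise ValueError(
                f"bone block [{lo.tolist()}, {hi.tolist()}] does not fit strictly "
                f"inside the slab grid on axis {k}"
            )
    return ilo, ihi


def _cap_uv_triangles(ulo: int, uhi: int, vlo: int, vhi: int) -> list[tuple]:
    """CCW triangulation of the rectangle [ulo,uhi]x[vlo,vhi] that uses
    only its perimeter grid nodes, traverses every perimeter edge exactly
    once, and contains no degenerate triangles: a fan strip along the
    subdivided bottom and top rows, plain rectangles in between."""
    tris: list[tuple] = []
    if vhi - vlo == 1:
        for u in range(ulo, uhi):  # single zig-zag strip
            tris.append(((u, vlo), (u + 1, vlo), (u, vhi)))
            tris.append(((u + 1, vlo), (u + 1, vhi), (u, vhi)))
        return tris
    apex_b = (ulo, vlo + 1)
    for u in range(ulo, uhi):
        tris.append(((u, vlo), (u + 1, vlo), apex_b))
    tris.append(((uhi, vlo), (uhi, vlo + 1), apex_b))
    for v in range(vlo + 1, vhi - 1):
        tris.append(((ulo, v), (uhi, v), (uhi, v + 1)))
        tris.append(((ulo, v), (uhi, v + 1), (ulo, v + 1)))
    apex_t = (uhi, vhi - 1)
    for u in range(uhi, ulo, -1):
        tris.append(((u, vhi), (u - 1, vhi), apex_t))
    tris.append(((ulo, vhi), (ulo, vhi - 1), apex_t))
    return tris


def _ring_cap(axis, c, ulo, uhi, vlo, vhi, nid, reverse: bool):
    """Triangulate the rectangular cut cross-section using only its
    perimeter grid nodes; normal along +axis unless reversed, so the cap
    closes the fragment surface watertight."""
    ua, va = (axis + 1) % 3, (axis + 2) % 3

    def node(u, v):
        idx = [0, 0, 0]
        idx[axis] = c
        idx[ua] = u
        idx[va] = v
        return nid(*idx)

    faces = np.array(
        [[node(*p) for p in tri] for tri in _cap_uv_triangles(ulo, uhi, vlo, vhi)],
        np.int64,
    )
    return faces[:, ::-1] if reverse else faces


def make_slab_scene(spec: FixtureSpec) -> Scene:
    """Build the full scene: conforming tet slab with block voids, closed
    fragment surfaces (vertex-identical with the tissue at the interface),
    face groups, LBS weights and the assembled coupling system."""
    nx, ny, nz = spec.grid_resolution
    dims = spec.slab_dimensions
    axes = [np.linspace(0.0, dims[k], (nx, ny, nz)[k] + 1) for k in range(3)]
    cell = dims / np.array([nx, ny, nz])

    blocks = [_snap_block(lo, hi, axes) for lo, hi in spec.bone_blocks]
    for a in range(len(blocks)):
        for b in range(a + 1, len(blocks)):
            lo1, hi1 = blocks[a]
            lo2, hi2 = blocks[b]
            if np.all(lo1 < hi2) and np.all(lo2 < hi1):
                raise ValueError(f"bone blocks {a} and {b} overlap")

    def nid(ix, iy, iz):
        return (ix * (ny + 1) + iy) * (nz + 1) + iz

    gx, gy, gz = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    all_nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def cell_void(ix, iy, iz):
        for lo, hi in blocks:
            if (lo[0] <= ix < hi[0]) and (lo[1] <= iy < hi[1]) and (lo[2] <= iz < hi[2]):
                return True
        return False

    tets = []
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if cell_void(ix, iy, iz):
                    continue
                corners = np.array(
                    [
                        nid(ix + dx, iy + dy, iz + dz)
                        for dz in (0, 1)
                        for dy in (0, 1)
                        for dx in (0, 1)
                    ]
                )
                # corners above are ordered z-major; remap to bit order
                corners = corners[[0, 1, 2, 3, 4, 5, 6, 7]]
                pattern = _TETS_EVEN if (ix + iy + iz) % 2 == 0 else _TETS_ODD
                tets.extend(corners[pattern])
    tets = np.array(tets, np.int64).reshape(-1, 4)
    # orient positively *before* extracting boundary faces, so the
    # fragment surfaces inherit a consistent outward orientation
    xx = all_nodes[tets]
    neg = np.linalg.det(xx[:, 1:] - xx[:, :1]) < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]

    # fragment/cap faces reference grid nodes; build them before compaction
    frag_faces_grid: dict[str, np.ndarray] = {}
    interface_faces_grid: list[np.ndarray] = []

    # boundary faces of the (uncompacted) tet set
    from .geometry import _TET_FACES

    faces_all = tets[:, _TET_FACES].reshape(-1, 3)
    und = np.sort(faces_all, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    bfaces = faces_all[counts[inv] == 1]

    grid_idx = np.column_stack(np.unravel_index(np.arange(len(all_nodes)),
                                                (nx + 1, ny + 1, nz + 1)))

    def block_boundary_faces(lo, hi):
        """Tissue boundary faces lying on the block's surface."""
        fi = grid_idx[bfaces]  # (nb, 3 verts, 3 axes)
        inside = np.all((fi >= lo) & (fi <= hi), axis=(1, 2))
        on_plane = np.zeros(len(bfaces), bool)
        for k in range(3):
            for c in (lo[k], hi[k]):
                on_plane |= np.all(fi[:, :, k] == c, axis=1)
        return bfaces[inside & on_plane]

    fragments: list[RigidFragment] = []
    for bi, (lo, hi) in enumerate(blocks):
        name = f"block{bi}"
        tissue_faces = block_boundary_faces(lo, hi)
        if len(tissue_faces) == 0:
            raise MeshValidationError(f"block {bi} produced no interface faces")
        interface_faces_grid.append(tissue_faces)
        block_faces = tissue_faces[:, ::-1]  # outward from the block
        cuts = spec.cut_planes[bi]
        if not cuts:
            frag_faces_grid[name] = block_faces
            continue
        if len(cuts) > 1:
            raise ValueError("at most one cut plane per block is supported")
        point, normal = cuts[0]
        point = np.asarray(point, float)
        normal = np.asarray(normal, float)
        axis = int(np.argmax(np.abs(normal)))
        axis_aligned = np.abs(normal / np.linalg.norm(normal))[axis] > 1.0 - 1e-12
        centroids = all_nodes[block_faces].mean(axis=1)
        if axis_aligned:
            # classify against the snapped plane so side faces and cap agree
            ci = int(np.argmin(np.abs(axes[axis] - point[axis])))
            if not lo[axis] < ci < hi[axis]:
                raise ValueError(f"cut plane misses block {bi} along axis {axis}")
            side = (centroids[:, axis] - axes[axis][ci]) * normal[axis] > 0.0
        else:
            side = (centroids - point) @ normal > 0.0
        halves = {f"{name}_0": block_faces[~side], f"{name}_1": block_faces[side]}
        if axis_aligned:
            ua, va = (axis + 1) % 3, (axis + 2) % 3
            cap_neg = _ring_cap(axis, ci, lo[ua], hi[ua], lo[va], hi[va], nid,
                                reverse=normal[axis] < 0)
            halves[f"{name}_0"] = np.vstack([halves[f"{name}_0"], cap_neg])
            halves[f"{name}_1"] = np.vstack([halves[f"{name}_1"], cap_neg[:, ::-1]])
        frag_faces_grid.update(halves)

    # compact nodes used by tets or any fragment face
    used = np.zeros(len(all_nodes), bool)
    used[np.unique(tets)] = True
    for ff in frag_faces_grid.values():
        used[np.unique(ff)] = True
    new_id = np.full(len(all_nodes), -1, np.int64)
    new_id[used] = np.arange(used.sum())
    nodes = all_nodes[used].copy()
    tets = new_id[tets]

    # seeded jitter on strictly interior, non-interface nodes
    if spec.jitter_fraction > 0.0:
        gi = grid_idx[used]
        interior = np.all(gi > 0, axis=1) & (gi[:, 0] < nx) & (gi[:, 1] < ny) & (gi[:, 2] < nz)
        for lo, hi in blocks:
            on_block = np.all((gi >= lo) & (gi <= hi), axis=1)
            interior &= ~on_block
        rng = np.random.default_rng(spec.seed)
        delta = rng.uniform(-1.0, 1.0, (int(interior.sum()), 3)) * (
            spec.jitter_fraction * cell
        )
        nodes[interior] += delta
        x = nodes[tets]
        vols = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
        if np.any(vols <= 0):
            raise MeshValidationError("jitter inverted an element; lower jitter_fraction")

    mesh = TetMesh(nodes, tets)

    for fname, ff in frag_faces_grid.items():
        surf = SurfaceMesh(mesh.rest_positions, new_id[ff])
        fragments.append(RigidFragment(fname, surf))
    fragments.sort(key=lambda f: f.id)

    interface = None
    weight_field = None
    assignment = None
    if interface_faces_grid:
        interface = SurfaceMesh(
            mesh.rest_positions, new_id[np.vstack(interface_faces_grid)]
        )
        assignment = assign_face_groups(interface, fragments)
        weight_field = lbs_weight_field(assignment, interface, spec.lbs_ramp_mm)

    fixed_nodes = np.empty(0, np.int64)
    if spec.fixed_region != "none":
        k = "xyz".index(spec.fixed_region[0])
        target = 0.0 if spec.fixed_region.endswith("min") else dims[k]
        fixed_nodes = np.where(np.abs(mesh.rest_positions[:, k] - target) < 1e-9)[0]
        if weight_field is not None:
            fixed_nodes = np.setdiff1d(fixed_nodes, weight_field.node_ids)

    coupling = build_coupling(mesh, fixed_nodes, weight_field, fragments)
    return Scene(
        mesh=mesh,
        material=spec.material,
        fragments={f.id: f for f in fragments},
        coupling=coupling,
        interface=interface,
        assignment=assignment,
        weight_field=weight_field,
        fixed_nodes=fixed_nodes,
    )


def make_advance_plan(
    scene: Scene,
    fragment_id: str,
    advance_mm=(0.0, 0.0, 0.0),
    rotate_deg=(0.0, 0.0, 0.0),
    substeps: int = 10,
) -> list[TransformTrajectory]:
    """Plan moving one fragment by ``advance_mm`` with an axis-angle
    rotation ``rotate_deg`` (degrees) about its rest center of mass; all
    other fragments stay put.  Returns one substepped trajectory per
    fragment."""
    if fragment_id not in scene.fragments:
        raise ValueError(f"unknown fragment {fragment_id!r}")
    rotvec = np.deg2rad(np.asarray(rotate_deg, float))
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(rotvec).as_matrix()
    com = scene.fragments[fragment_id].rest_center_of_mass
    target = Transform(R, com - R @ com + np.asarray(advance_mm, float))
    plans = []
    for fid, frag in scene.fragments.items():
        tgt = target if fid == fragment_id else Transform.identity()
        plans.append(make_trajectory(frag, tgt, substeps))
    return plans
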