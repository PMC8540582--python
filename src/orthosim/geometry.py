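"""Mesh data types, file I/O and geometric queries.

All lengths are millimetres, volumes mm^3.  Surface meshes are triangle
soups with optional per-face integer group labels (used to mark
tissue--bone coupling regions).  Volume meshes are linear tetrahedra with
one integration point per element whose quadrature weight is the rest
volume of the tetrahedron.

Indices are 0-based internally; 1-based conventions of external formats
(OBJ, TetGen) are converted at the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "MeshFormatError",
    "MeshValidationError",
    "SurfaceMesh",
    "TetMesh",
    "Transform",
    "read_surface",
    "write_surface",
    "read_tet_mesh",
    "write_tet_mesh",
    "read_vtk",
    "write_vtk",
    "signed_distance_query",
    "closest_point_query",
    "winding_number",
]


class MeshFormatError(ValueError):
    """A mesh file does not parse under its declared format."""


class MeshValidationError(ValueError):
    """Mesh data violates a structural invariant."""


# --------------------------------------------------------------------------
# Surface meshes
# --------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangle mesh in mm.

    ``face_group_labels`` holds one integer per face (e.g. the bone
    fragment a tissue face is coupled to); ``group_names`` optionally maps
    label -> human-readable name.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_group_labels: np.ndarray | None = None
    vertex_normals: np.ndarray | None = None
    group_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (n, 3)")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise MeshValidationError("faces must be (m, 3)")
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)
        self.validate()

    def validate(self) -> None:
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            bad = np.where((self.faces < 0) | (self.faces >= n))[0]
            raise MeshValidationError(
                f"face indices out of range [0, {n}) in faces {sorted(set(bad.tolist()))}"
            )
        f = self.faces
        if f.size:
            degen = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if degen.any():
                raise MeshValidationError(
                    f"degenerate faces (repeated vertex): {np.where(degen)[0].tolist()}"
                )
        if self.face_group_labels is not None:
            self.face_group_labels = np.asarray(self.face_group_labels, dtype=np.int64)
            if len(self.face_group_labels) != len(self.faces):
                raise MeshValidationError("face_group_labels length mismatch")
        if self.vertex_normals is not None:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=np.float64)
            norms = np.linalg.norm(self.vertex_normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise MeshValidationError("vertex normals must have unit length")

    # -- derived quantities ------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        cr = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def face_normals(self) -> np.ndarray:
        t = self.triangles()
        cr = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        n = np.linalg.norm(cr, axis=1)
        n = np.where(n == 0.0, 1.0, n)
        return cr / n[:, None]

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def vertex_areas(self) -> np.ndarray:
        """One third of incident face area per vertex (barycentric lumping)."""
        areas = np.zeros(self.n_vertices)
        fa = self.face_areas() / 3.0
        for k in range(3):
            np.add.at(areas, self.faces[:, k], fa)
        return areas

    def area_weighted_vertex_normals(self) -> np.ndarray:
        vn = np.zeros_like(self.vertices)
        fn = self.face_normals() * self.face_areas()[:, None]
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        n = np.linalg.norm(vn, axis=1)
        n = np.where(n == 0.0, 1.0, n)
        return vn / n[:, None]

    def used_vertices(self) -> np.ndarray:
        return np.unique(self.faces)

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly two faces
        with opposite orientation (a watertight, consistently oriented 2-manifold)."""
        if self.n_faces == 0:
            return False
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        und = np.sort(e, axis=1)
        _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        if not np.all(counts == 2):
            return False
        # opposite orientation: directed edges must all be distinct
        dir_unique = np.unique(e, axis=0)
        return len(dir_unique) == len(e)

    def transformed(self, transform: "Transform") -> "SurfaceMesh":
        return SurfaceMesh(
            transform.apply(self.vertices),
            self.faces.copy(),
            None if self.face_group_labels is None else self.face_group_labels.copy(),
            None,
            dict(self.group_names),
        )

    def submesh(self, face_mask: np.ndarray, compact: bool = False) -> "SurfaceMesh":
        """Subset of faces; with ``compact`` unused vertices are dropped."""
        faces = self.faces[face_mask]
        labels = (
            None
            if self.face_group_labels is None
            else self.face_group_labels[face_mask]
        )
        if not compact:
            return SurfaceMesh(self.vertices, faces, labels, None, dict(self.group_names))
        used, inv = np.unique(faces, return_inverse=True)
        return SurfaceMesh(
            self.vertices[used], inv.reshape(faces.shape), labels, None, dict(self.group_names)
        )


def weld_vertices(mesh: SurfaceMesh, tolerance: float = 1e-6) -> SurfaceMesh:
    """Merge vertices closer than ``tolerance`` (mm) on a rounded grid and
    drop faces made degenerate by the merge (STL stores every triangle with
    its own vertex copies)."""
    key = np.round(mesh.vertices / tolerance).astype(np.int64)
    _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # keep original vertex order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    verts = mesh.vertices[first[order]]
    faces = rank[inv][mesh.faces]
    keep = ~(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    labels = None if mesh.face_group_labels is None else mesh.face_group_labels[keep]
    return SurfaceMesh(verts, faces[keep], labels, None, dict(mesh.group_names))


# --------------------------------------------------------------------------
# Rigid transforms
# --------------------------------------------------------------------------


@dataclass
class Transform:
    """Proper rigid transform x -> R x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.validate()

    def validate(self) -> None:
        R = self.rotation
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise MeshValidationError("rotation must be orthonormal with det +1")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis_angle, translation=(0.0, 0.0, 0.0)) -> "Transform":
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(np.asarray(axis_angle, float)).as_matrix(),
                   np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self after other."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)

    def axis_angle(self) -> np.ndarray:
        from scipy.spatial.transform import Rotation

        return Rotation.from_matrix(self.rotation).as_rotvec()


# --------------------------------------------------------------------------
# Tetrahedral meshes
# --------------------------------------------------------------------------

# outward boundary faces of a positively oriented tet (a, b, c, d)
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


@dataclass
class TetMesh:
    """Linear-tetrahedron volume mesh with precomputed shape-function data.

    ``element_basis[e]`` is the inverse rest edge matrix Dm^{-1} of element
    e; its rows are the shape-function gradients of local nodes 1..3 and
    the gradient of node 0 is minus their sum.  ``quadrature_weights[e]``
    is the rest volume, the single-point quadrature weight used when the
    total elastic energy is summed over elements.
    """

    rest_positions: np.ndarray
    tets: np.ndarray

    def __post_init__(self) -> None:
        self.rest_positions = np.ascontiguousarray(self.rest_positions, np.float64)
        self.tets = np.ascontiguousarray(self.tets, np.int64)
        if self.rest_positions.ndim != 2 or self.rest_positions.shape[1] != 3:
            raise MeshValidationError("rest_positions must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshValidationError("tets must be (m, 4)")
        n = len(self.rest_positions)
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= n:
            raise MeshValidationError("tet indices out of range")
        vol = self._signed_volumes()
        inverted = vol < 0
        if inverted.any():
            # reorient by swapping two indices
            self.tets[inverted] = self.tets[inverted][:, [0, 1, 3, 2]]
            vol = np.abs(vol)
        if np.any(vol < 1e-9):
            bad = np.where(vol < 1e-9)[0]
            raise MeshValidationError(f"zero-volume tets (< 1e-9 mm^3): {bad.tolist()}")
        self._recompute_basis()

    def _signed_volumes(self) -> np.ndarray:
        x = self.rest_positions[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.linalg.det(d) / 6.0

    def _recompute_basis(self) -> None:
        x = self.rest_positions[self.tets]
        dm = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)  # columns are edges
        self.quadrature_weights = np.linalg.det(dm) / 6.0
        self.element_basis = np.linalg.inv(dm)

    @property
    def n_nodes(self) -> int:
        return len(self.rest_positions)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    @cached_property
    def shape_gradients(self) -> np.ndarray:
        """(m, 4, 3) gradients dN_a/dX of the four linear shape functions."""
        g = np.empty((self.n_elements, 4, 3))
        g[:, 1:] = self.element_basis  # rows of Dm^{-1}
        g[:, 0] = -self.element_basis.sum(axis=1)
        return g

    @cached_property
    def boundary_surface(self) -> SurfaceMesh:
        """Exterior faces (incident to exactly one tet), outward oriented,
        indexing into the full node array."""
        faces = self.tets[:, _TET_FACES].reshape(-1, 3)
        und = np.sort(faces, axis=1)
        _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        boundary = counts[inv] == 1
        return SurfaceMesh(self.rest_positions, faces[boundary])

    def total_volume(self) -> float:
        return float(self.quadrature_weights.sum())

    def with_positions(self, positions: np.ndarray) -> "TetMesh":
        """Same connectivity with new nodal positions (re-derives basis)."""
        return TetMesh(np.asarray(positions, float).reshape(-1, 3), self.tets.copy())


# --------------------------------------------------------------------------
# Closest-point / signed-distance queries
# --------------------------------------------------------------------------


def _closest_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest point on each triangle (a, b, c) to each point p (all (k,3)).

    Vectorized version of the standard region classification
    (Ericson, Real-Time Collision Detection, ch. 5).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex a
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex b
    settle((d6 >= 0) & (d5 <= d6), c)  # vertex c

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0.0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge ab

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0.0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge ac

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0.0, (d4 - d3) / denom_bc, 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))

    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0.0, vb / denom, 0.0)
        w = np.where(denom != 0.0, vc / denom, 0.0)
    settle(np.ones(len(p), bool), a + v[:, None] * ab + w[:, None] * ac)  # interior
    return out


def closest_point_query(points: np.ndarray, surface: SurfaceMesh, chunk: int = 4_000_000):
    """Unsigned closest point on a triangle mesh.

    Returns ``(distances, closest_points, face_indices)``.  Every triangle
    is scanned per query point (chunked for memory); mesh sizes in this
    package are small enough that this exact scan is the robust choice.
    """
    points = np.atleast_2d(np.asarray(points, float))
    tri = surface.triangles()
    m = len(tri)
    if m == 0:
        raise MeshValidationError("surface has no faces")
    q = len(points)
    dist = np.empty(q)
    closest = np.empty((q, 3))
    fidx = np.empty(q, dtype=np.int64)
    step = max(1, chunk // max(m, 1))
    for s in range(0, q, step):
        p = points[s : s + step]
        k = len(p)
        pp = np.repeat(p, m, axis=0)
        a = np.tile(tri[:, 0], (k, 1))
        b = np.tile(tri[:, 1], (k, 1))
        c = np.tile(tri[:, 2], (k, 1))
        cp = _closest_on_triangles(pp, a, b, c).reshape(k, m, 3)
        d2 = np.einsum("kmi,kmi->km", cp - p[:, None, :], cp - p[:, None, :])
        j = np.argmin(d2, axis=1)
        rows = np.arange(k)
        dist[s : s + step] = np.sqrt(d2[rows, j])
        closest[s : s + step] = cp[rows, j]
        fidx[s : s + step] = j
    return dist, closest, fidx


def winding_number(points: np.ndarray, surface: SurfaceMesh, chunk: int = 2_000_000) -> np.ndarray:
    """Generalized winding number (solid-angle sum / 4pi) of each point.

    ~1 inside a closed outward-oriented surface, ~0 outside; degrades
    gracefully on nearly closed meshes.
    """
    points = np.atleast_2d(np.asarray(points, float))
    tri = surface.triangles()
    m = len(tri)
    q = len(points)
    wn = np.empty(q)
    step = max(1, chunk // max(m, 1))
    for s in range(0, q, step):
        p = points[s : s + step]
        a = tri[None, :, 0] - p[:, None]
        b = tri[None, :, 1] - p[:, None]
        c = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        det = np.einsum("kmi,kmi->km", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("kmi,kmi->km", a, b) * lc
            + np.einsum("kmi,kmi->km", b, c) * la
            + np.einsum("kmi,kmi->km", c, a) * lb
        )
        omega = 2.0 * np.arctan2(det, denom)
        wn[s : s + step] = omega.sum(axis=1) / (4.0 * np.pi)
    return wn


def signed_distance_query(
    points, surface: SurfaceMesh, allow_open: bool = False
) -> np.ndarray:
    """Signed closest-point distance (mm): negative inside the enclosed
    volume, matching the convention that a simulated surface lying inside
    the reference scan reports negative error.

    Inside/outside is decided by the generalized winding number
    (threshold 0.5).  For open surfaces pass ``allow_open``; the sign then
    comes from the nearest face normal.
    """
    points = np.atleast_2d(np.asarray(points, float))
    dist, closest, fidx = closest_point_query(points, surface)
    if surface.is_closed():
        inside = winding_number(points, surface) > 0.5
        sign = np.where(inside, -1.0, 1.0)
    elif allow_open:
        normals = surface.face_normals()[fidx]
        outside = np.einsum("ij,ij->i", points - closest, normals) >= 0.0
        sign = np.where(outside, 1.0, -1.0)
    else:
        raise MeshValidationError(
            "surface is not closed; pass allow_open=True to sign by face normal"
        )
    return sign * dist


# --------------------------------------------------------------------------
# OBJ I/O (hand-parsed: group tags carry coupling face groups)
# --------------------------------------------------------------------------


def _read_obj(path: str) -> SurfaceMesh:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    labels: list[int] = []
    group_names: dict[int, str] = {}
    name_to_label: dict[str, int] = {}
    current = 0
    saw_group = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: vertex needs 3 coordinates")
                try:
                    vertices.append([float(parts[1]), float(parts[2]), float(parts[3])])
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: {exc}") from None
            elif tag == "g" or tag == "o":
                saw_group = True
                name = " ".join(parts[1:]) or "default"
                if name not in name_to_label:
                    name_to_label[name] = len(name_to_label)
                    group_names[name_to_label[name]] = name
                current = name_to_label[name]
            elif tag == "f":
                idx = []
                for tok in parts[1:]:
                    head = tok.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError:
                        raise MeshFormatError(
                            f"{path}:{lineno}: bad face index {tok!r}"
                        ) from None
                    if i == 0:
                        raise MeshValidationError(
                            f"{path}:{lineno}: face index 0 in a 1-based OBJ file"
                        )
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                if len(idx) < 3:
                    raise MeshFormatError(f"{path}:{lineno}: face with < 3 vertices")
                for k in range(1, len(idx) - 1):  # fan triangulation
                    faces.append([idx[0], idx[k], idx[k + 1]])
                    labels.append(current)
    return SurfaceMesh(
        np.array(vertices, float).reshape(-1, 3),
        np.array(faces, np.int64).reshape(-1, 3),
        np.array(labels, np.int64) if saw_group else None,
        None,
        group_names,
    )


def _write_obj(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# orthosim surface mesh\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        if mesh.face_group_labels is None:
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
        else:
            order = np.argsort(mesh.face_group_labels, kind="stable")
            last = None
            for i in order:
                lab = int(mesh.face_group_labels[i])
                if lab != last:
                    fh.write(f"g {mesh.group_names.get(lab, f'group_{lab}')}\n")
                    last = lab
                f = mesh.faces[i]
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def read_surface(path: str, format: str | None = None) -> SurfaceMesh:
    """Read an OBJ/STL/PLY surface.  OBJ group tags become face-group
    labels; STL vertices are welded at 1e-6 mm (the format duplicates
    them per triangle)."""
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).upper()
    if fmt == "OBJ":
        return _read_obj(path)
    if fmt in ("STL", "PLY"):
        import trimesh

        try:
            tm = trimesh.load(path, file_type=fmt.lower(), process=False, force="mesh")
        except Exception as exc:  # noqa: BLE001 - re-raise with format context
            raise MeshFormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
        mesh = SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
        if fmt == "STL":
            mesh = weld_vertices(mesh, 1e-6)
        return mesh
    raise MeshFormatError(f"unsupported surface format {fmt!r}")


def write_surface(mesh: SurfaceMesh, path: str, format: str | None = None) -> None:
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).upper()
    if fmt == "OBJ":
        _write_obj(mesh, path)
        return
    if fmt in ("STL", "PLY"):
        import trimesh

        trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(path)
        return
    raise MeshFormatError(f"unsupported surface format {fmt!r}")


# --------------------------------------------------------------------------
# TetGen .node / .ele I/O
# --------------------------------------------------------------------------


def _tokens(path: str) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                rows.append(line.split())
    return rows


def read_tet_mesh(node_path: str, ele_path: str) -> TetMesh:
    """Read a TetGen .node/.ele pair.

    The index base (0 or 1) is taken from the first node's index, as the
    mesher writes it; a .ele file whose indices fall outside the node
    range under that base is rejected.
    """
    nrows = _tokens(node_path)
    if not nrows:
        raise MeshFormatError(f"{node_path}: missing header")
    try:
        n_nodes = int(nrows[0][0])
    except (ValueError, IndexError):
        raise MeshFormatError(f"{node_path}: malformed header {nrows[0]!r}") from None
    body = nrows[1 : 1 + n_nodes]
    if len(body) != n_nodes:
        raise MeshFormatError(f"{node_path}: expected {n_nodes} node records")
    ids = np.array([int(r[0]) for r in body])
    base = int(ids.min())
    if base not in (0, 1) or not np.array_equal(np.sort(ids), np.arange(base, base + n_nodes)):
        raise MeshFormatError(f"{node_path}: node indices must be contiguous from 0 or 1")
    coords = np.empty((n_nodes, 3))
    for r in body:
        coords[int(r[0]) - base] = [float(r[1]), float(r[2]), float(r[3])]

    erows = _tokens(ele_path)
    if not erows:
        raise MeshFormatError(f"{ele_path}: missing header")
    try:
        n_ele = int(erows[0][0])
        npt = int(erows[0][1]) if len(erows[0]) > 1 else 4
    except ValueError:
        raise MeshFormatError(f"{ele_path}: malformed header {erows[0]!r}") from None
    if npt != 4:
        raise MeshFormatError(f"{ele_path}: only 4-node tetrahedra supported, got {npt}")
    ebody = erows[1 : 1 + n_ele]
    if len(ebody) != n_ele:
        raise MeshFormatError(f"{ele_path}: expected {n_ele} element records")
    tets = np.array([[int(t) for t in r[1:5]] for r in ebody], np.int64)
    if tets.size and (tets.min() < base or tets.max() >= base + n_nodes):
        raise MeshFormatError(
            f"{ele_path}: element indices outside node range (index base {base}); "
            "mixed index bases are not supported"
        )
    return TetMesh(coords, tets - base)


def write_tet_mesh(mesh: TetMesh, node_path: str, ele_path: str) -> None:
    """Write TetGen-dialect .node/.ele (1-based, the mesher's default)."""
    with open(node_path, "w") as fh:
        fh.write(f"{mesh.n_nodes} 3 0 0\n")
        for i, x in enumerate(mesh.rest_positions, 1):
            fh.write(f"{i} {x[0]:.17g} {x[1]:.17g} {x[2]:.17g}\n")
    with open(ele_path, "w") as fh:
        fh.write(f"{mesh.n_elements} 4 0\n")
        for i, t in enumerate(mesh.tets + 1, 1):
            fh.write(f"{i} {t[0]} {t[1]} {t[2]} {t[3]}\n")


# --------------------------------------------------------------------------
# Legacy VTK I/O (ASCII unstructured grid with named point scalars)
# --------------------------------------------------------------------------


def write_vtk(mesh, point_scalars: dict[str, np.ndarray] | None, path: str) -> None:
    """Write a legacy-ASCII VTK unstructured grid.

    ``mesh`` may be a TetMesh (cell type 10) or SurfaceMesh (cell type 5).
    ``point_scalars`` maps array name -> per-vertex values, e.g.
    ``{"signed_error_mm": err}``.
    """
    point_scalars = point_scalars or {}
    if isinstance(mesh, TetMesh):
        points, cells, ctype = mesh.rest_positions, mesh.tets, 10
    elif isinstance(mesh, SurfaceMesh):
        points, cells, ctype = mesh.vertices, mesh.faces, 5
    else:
        raise TypeError(f"cannot write {type(mesh).__name__} to VTK")
    for name, arr in point_scalars.items():
        if len(np.asarray(arr)) != len(points):
            raise MeshValidationError(
                f"scalar array {name!r} has {len(np.asarray(arr))} values for {len(points)} points"
            )
    k = cells.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\northosim output\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"CELLS {len(cells)} {len(cells) * (k + 1)}\n")
        for c in cells:
            fh.write(str(k) + " " + " ".join(str(int(i)) for i in c) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        fh.writelines(f"{ctype}\n" for _ in range(len(cells)))
        if point_scalars:
            fh.write(f"POINT_DATA {len(points)}\n")
            for name, arr in point_scalars.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.writelines(f"{float(v):.17g}\n" for v in np.asarray(arr, float))


def read_vtk(path: str):
    """Read back a legacy-ASCII VTK unstructured grid written by
    :func:`write_vtk`.  Returns ``(mesh, point_scalars)``."""
    with open(path) as fh:
        tokens = fh.read().split()

    def find(word: str, start: int = 0) -> int:
        for i in range(start, len(tokens)):
            if tokens[i] == word:
                return i
        raise MeshFormatError(f"{path}: missing {word} section")

    ip = find("POINTS")
    npts = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3 : ip + 3 + 3 * npts], float).reshape(npts, 3)
    ic = find("CELLS")
    ncell = int(tokens[ic + 1])
    total = int(tokens[ic + 2])
    flat = np.array(tokens[ic + 3 : ic + 3 + total], np.int64)
    k = int(flat[0])
    cells = flat.reshape(ncell, k + 1)[:, 1:]
    itype = find("CELL_TYPES")
    ctype = int(tokens[itype + 2])
    scalars: dict[str, np.ndarray] = {}
    i = itype + 2 + ncell
    while i < len(tokens):
        if tokens[i] == "SCALARS":
            name = tokens[i + 1]
            j = i + 2
            while tokens[j] != "LOOKUP_TABLE":
                j += 1
            j += 2  # skip LOOKUP_TABLE <name>
            scalars[name] = np.array(tokens[j : j + npts], float)
            i = j + npts
        else:
            i += 1
    if ctype == 10:
        return TetMesh(coords, cells), scalars
    return SurfaceMesh(coords, cells), scalars
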