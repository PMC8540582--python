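"""Tissue fixing/coupling constraints and smooth coupling at bone cuts.

Coupled soft-tissue DoFs are expressed as a linear function of the free
DoFs z plus an offset:  S x = A z + c, with S a 0/1 selection matrix and
S~ its complement selecting the free soft DoFs.  The full state is then
reconstructed as  x = S~^T z + S^T (A z + c), which satisfies the
constraints exactly by construction -- no Lagrange multipliers, no
penalty drift.  For tissue fixed in space and for couplings to
*prescribed* fragments A = 0 and the fragment poses enter only through c;
for free fragments the rows of A carry the linearized rigid-body map
(identity in the COM translation, minus the cross-product matrix of the
rotated rest offset in the incremental rotation).

Across an osteotomy the tissue is not bonded to a single fragment:
linear blend skinning (LBS) weights blend the rigid maps of the two
fragments meeting at the cut, 0.5/0.5 on the cut itself ramping linearly
to 1.0/0.0 over ``ramp_mm`` (default 10 mm = 1 cm).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import scipy.sparse as sp

from .geometry import SurfaceMesh, TetMesh, closest_point_query
from .rigid import RigidFragment

__all__ = [
    "NodeKind",
    "FaceGroupAssignment",
    "WeightField",
    "CouplingSystem",
    "assign_face_groups",
    "lbs_weight_field",
    "build_coupling",
    "reconstruct_full_dofs",
    "coupling_residual",
]


class NodeKind(IntEnum):
    FREE = 0
    FIXED = 1
    BONDED = 2
    LBS = 3


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


# --------------------------------------------------------------------------
# Face groups on the matched tissue-bone interface
# --------------------------------------------------------------------------


@dataclass
class FaceGroupAssignment:
    """Which bone fragment each coupled interface face belongs to.

    ``cut_interface_vertices`` are the interface vertices sitting between
    differently-labeled face groups, i.e. on the bone cut.
    """

    coupled_faces: np.ndarray  # indices into the interface mesh faces
    fragment_of_face: list[str]  # fragment id per coupled face
    cut_interface_vertices: np.ndarray  # vertex indices (interface mesh)


def assign_face_groups(
    interface: SurfaceMesh, fragments: list[RigidFragment], tol: float = 1e-9
) -> FaceGroupAssignment:
    """Label every interface face with the nearest fragment surface.

    The interface is the tissue-side copy of the matched tissue--bone
    surface, so each face centroid lies (near-)exactly on one fragment's
    surface.  Ties within ``tol`` go to the lexicographically smallest
    fragment id.
    """
    if not fragments:
        raise ValueError("fragment list is empty")
    frags = sorted(fragments, key=lambda f: f.id)
    centroids = interface.face_centroids()
    dists = np.column_stack(
        [closest_point_query(centroids, f.surface)[0] for f in frags]
    )
    best = dists.min(axis=1)
    # first (lexicographically smallest id) within tol of the minimum
    label_idx = np.argmax(dists <= best[:, None] + tol, axis=1)
    labels = [frags[i].id for i in label_idx]

    # vertices incident to faces of >= 2 distinct labels
    vert_labels: dict[int, set[str]] = {}
    for face, lab in zip(interface.faces, labels):
        for v in face:
            vert_labels.setdefault(int(v), set()).add(lab)
    cut_vertices = np.array(
        sorted(v for v, labs in vert_labels.items() if len(labs) >= 2), dtype=np.int64
    )
    return FaceGroupAssignment(
        np.arange(interface.n_faces), labels, cut_vertices
    )


# --------------------------------------------------------------------------
# LBS weight field
# --------------------------------------------------------------------------


@dataclass
class WeightField:
    """Per-node fragment blending weights on the coupled interface.

    Nodes farther than the ramp from every cut carry a single weight of
    1.0 for their own fragment; nodes inside the ramp carry two weights
    summing to 1.
    """

    node_ids: np.ndarray  # interface vertex ids (= tet-mesh node ids)
    fragment_ids: list[list[str]]
    weights: list[list[float]]

    def as_dict(self) -> dict[int, dict[str, float]]:
        return {
            int(n): dict(zip(f, w))
            for n, f, w in zip(self.node_ids, self.fragment_ids, self.weights)
        }


def lbs_weight_field(
    assignment: FaceGroupAssignment,
    interface: SurfaceMesh,
    ramp_mm: float = 10.0,
) -> WeightField:
    """Linear-blend-skinning weights for the coupled interface nodes.

    A node at Euclidean distance d from the nearest cut-interface vertex
    receives weight 0.5 + 0.5 * min(d, ramp) / ramp for its own fragment
    and the complement for the nearest fragment across the cut; at the cut
    both fragments weigh 0.5, and from ``ramp_mm`` (1 cm by default)
    outwards the coupling is rigidly bonded to the node's own fragment.
    """
    if ramp_mm <= 0.0:
        raise ValueError("ramp_mm must be positive")
    faces = interface.faces
    labels = assignment.fragment_of_face
    node_ids = np.unique(faces)

    # own fragment: majority label of incident faces, smallest id on ties
    incident: dict[int, Counter] = {int(v): Counter() for v in node_ids}
    for face, lab in zip(faces, labels):
        for v in face:
            incident[int(v)][lab] += 1
    own: dict[int, str] = {}
    for v, cnt in incident.items():
        top = max(cnt.values())
        own[v] = min(lab for lab, c in cnt.items() if c == top)

    distinct = sorted(set(labels))
    cut = assignment.cut_interface_vertices
    frag_ids: list[list[str]] = []
    wts: list[list[float]] = []

    if len(distinct) < 2 or len(cut) == 0:
        for v in node_ids:
            frag_ids.append([own[int(v)]])
            wts.append([1.0])
        return WeightField(node_ids, frag_ids, wts)

    pos = interface.vertices[node_ids]
    cut_pos = interface.vertices[cut]
    from scipy.spatial import cKDTree

    d_cut, _ = cKDTree(cut_pos).query(pos)

    # distance from each node to each label's face subset (to pick the
    # nearest fragment on the other side of the cut)
    label_arr = np.asarray(labels)
    d_label = {}
    for lab in distinct:
        sub = interface.submesh(label_arr == lab)
        d_label[lab] = closest_point_query(pos, sub)[0]

    for k, v in enumerate(node_ids):
        o = own[int(v)]
        d = float(d_cut[k])
        if d >= ramp_mm:
            frag_ids.append([o])
            wts.append([1.0])
            continue
        others = [lab for lab in distinct if lab != o]
        other = min(others, key=lambda lab: (d_label[lab][k], lab))
        w_own = 0.5 + 0.5 * min(d, ramp_mm) / ramp_mm
        frag_ids.append([o, other])
        wts.append([w_own, 1.0 - w_own])
    return WeightField(node_ids, frag_ids, wts)


# --------------------------------------------------------------------------
# Coupling system (selection matrices, linear map, offsets)
# --------------------------------------------------------------------------


@dataclass
class CouplingSystem:
    """Selection matrices and the linear constraint map S x = A z + c.

    z stacks the free soft DoFs followed by 6 DoFs (COM translation,
    incremental rotation) per *free* fragment; prescribed fragments have
    no DoFs and enter only through the offset c, refreshed per substep via
    :meth:`update_offsets`.
    """

    n_nodes: int
    constrained_selector: sp.csr_matrix  # S
    free_selector: sp.csr_matrix  # S~ (free soft DoFs only)
    linear_map: sp.csr_matrix  # A (n_constrained_dofs x nz)
    offset: np.ndarray  # c
    node_kind: np.ndarray  # per-node NodeKind
    free_fragment_ids: list[str] = field(default_factory=list)
    # bookkeeping for offset refresh: per coupled node, its blend entries
    _coupled_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    _entries: list[list[tuple[str, float, np.ndarray]]] = field(default_factory=list)
    _fixed_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    _fixed_targets: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    _constrained_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def n_free_soft_dofs(self) -> int:
        return self.free_selector.shape[0]

    @property
    def n_z(self) -> int:
        return self.n_free_soft_dofs + 6 * len(self.free_fragment_ids)

    @property
    def n_constrained_dofs(self) -> int:
        return self.constrained_selector.shape[0]

    def jacobian(self) -> sp.csr_matrix:
        """J with x = J z + S^T c, i.e. J = [S~^T | 0] + S^T A."""
        J_soft = self.free_selector.T
        if self.n_z > self.n_free_soft_dofs:
            pad = sp.csr_matrix((3 * self.n_nodes, self.n_z - self.n_free_soft_dofs))
            J_soft = sp.hstack([J_soft, pad], format="csr")
        return (J_soft + self.constrained_selector.T @ self.linear_map).tocsr()

    def update_offsets(self, fragments: dict[str, RigidFragment]) -> None:
        """Recompute c (and the free-fragment rows of A) from the current
        fragment poses."""
        c = np.zeros(self.n_constrained_dofs)
        # fixed nodes first, in row order
        node_row = {int(n): 3 * i for i, n in enumerate(self._constrained_nodes)}
        for n, tgt in zip(self._fixed_nodes, self._fixed_targets):
            r = node_row[int(n)]
            c[r : r + 3] = tgt
        rows, cols, vals = [], [], []
        nzs = self.n_free_soft_dofs
        rigid_col = {fid: nzs + 6 * k for k, fid in enumerate(self.free_fragment_ids)}
        for node, entries in zip(self._coupled_nodes, self._entries):
            r = node_row[int(node)]
            for fid, w, X_rel in entries:
                frag = fragments[fid]
                rx = frag.rotation @ X_rel
                if fid in rigid_col:
                    c[r : r + 3] += w * rx
                    c0 = rigid_col[fid]
                    blk_t = w * np.eye(3)
                    blk_r = -w * _skew(rx)
                    for i in range(3):
                        for j in range(3):
                            rows.extend([r + i, r + i])
                            cols.extend([c0 + j, c0 + 3 + j])
                            vals.extend([blk_t[i, j], blk_r[i, j]])
                else:
                    c[r : r + 3] += w * (rx + frag.center_of_mass)
        self.offset = c
        self.linear_map = sp.coo_matrix(
            (vals, (rows, cols)), shape=(self.n_constrained_dofs, self.n_z)
        ).tocsr()

    def initial_z(self, positions: np.ndarray, fragments: dict[str, RigidFragment]) -> np.ndarray:
        """Free vector matching given full positions and fragment poses."""
        z = np.zeros(self.n_z)
        z[: self.n_free_soft_dofs] = self.free_selector @ np.asarray(positions, float).ravel()
        for k, fid in enumerate(self.free_fragment_ids):
            c0 = self.n_free_soft_dofs + 6 * k
            z[c0 : c0 + 3] = fragments[fid].center_of_mass
            z[c0 + 3 : c0 + 6] = fragments[fid].incremental_rotation
        return z


def build_coupling(
    mesh: TetMesh,
    fixed_nodes,
    weight_field: WeightField | None,
    fragments: list[RigidFragment],
    fixed_targets: np.ndarray | None = None,
) -> CouplingSystem:
    """Assemble the selection matrices, linear map and offsets.

    ``fixed_nodes`` are clamped (to their rest positions unless
    ``fixed_targets`` is given); nodes of ``weight_field`` follow the
    blended rigid maps of their fragments.  Fragments with
    ``prescribed=False`` contribute 6 solved DoFs each, appended to z.
    """
    n = mesh.n_nodes
    fixed_nodes = np.asarray(sorted(set(map(int, np.atleast_1d(fixed_nodes)))), np.int64) \
        if len(np.atleast_1d(fixed_nodes)) else np.empty(0, np.int64)
    frag_by_id = {f.id: f for f in fragments}

    coupled_nodes = (
        np.asarray(weight_field.node_ids, np.int64)
        if weight_field is not None
        else np.empty(0, np.int64)
    )
    overlap = np.intersect1d(fixed_nodes, coupled_nodes)
    if len(overlap):
        raise ValueError(f"nodes both fixed and coupled: {overlap.tolist()}")

    node_kind = np.full(n, NodeKind.FREE, dtype=np.int64)
    node_kind[fixed_nodes] = NodeKind.FIXED
    entries: list[list[tuple[str, float, np.ndarray]]] = []
    if weight_field is not None:
        for node, fids, ws in zip(
            weight_field.node_ids, weight_field.fragment_ids, weight_field.weights
        ):
            node_kind[node] = NodeKind.BONDED if len(fids) == 1 else NodeKind.LBS
            row = []
            for fid, w in zip(fids, ws):
                frag = frag_by_id[fid]
                X_rel = mesh.rest_positions[node] - frag.rest_center_of_mass
                row.append((fid, float(w), X_rel))
            entries.append(row)

    constrained_nodes = np.concatenate([fixed_nodes, coupled_nodes])
    order = np.argsort(constrained_nodes, kind="stable")
    # keep a canonical (sorted by node id) row order
    constrained_nodes_sorted = constrained_nodes[order]
    is_fixed_row = np.concatenate(
        [np.ones(len(fixed_nodes), bool), np.zeros(len(coupled_nodes), bool)]
    )[order]

    cdofs = (3 * constrained_nodes_sorted[:, None] + np.arange(3)).ravel()
    m = len(cdofs)
    S = sp.csr_matrix(
        (np.ones(m), (np.arange(m), cdofs)), shape=(m, 3 * n)
    )
    free_mask = np.ones(3 * n, bool)
    free_mask[cdofs] = False
    fdofs = np.where(free_mask)[0]
    St = sp.csr_matrix(
        (np.ones(len(fdofs)), (np.arange(len(fdofs)), fdofs)), shape=(len(fdofs), 3 * n)
    )

    free_fragment_ids = sorted(f.id for f in fragments if not f.prescribed)

    if fixed_targets is None:
        fixed_tg = mesh.rest_positions[fixed_nodes]
    else:
        fixed_tg = np.asarray(fixed_targets, float).reshape(len(fixed_nodes), 3)

    # entries reordered to sorted node order
    entry_by_node = dict(zip(coupled_nodes.tolist(), entries))
    coupled_sorted = constrained_nodes_sorted[~is_fixed_row]
    entries_sorted = [entry_by_node[int(v)] for v in coupled_sorted]

    cs = CouplingSystem(
        n_nodes=n,
        constrained_selector=S,
        free_selector=St,
        linear_map=sp.csr_matrix((m, len(fdofs) + 6 * len(free_fragment_ids))),
        offset=np.zeros(m),
        node_kind=node_kind,
        free_fragment_ids=free_fragment_ids,
        _coupled_nodes=coupled_sorted,
        _entries=entries_sorted,
        _fixed_nodes=fixed_nodes,
        _fixed_targets=fixed_tg,
        _constrained_nodes=constrained_nodes_sorted,
    )
    cs.update_offsets(frag_by_id)
    return cs


def reconstruct_full_dofs(coupling: CouplingSystem, z: np.ndarray) -> np.ndarray:
    """x = S~^T z + S^T (A z + c); satisfies the couplings exactly."""
    z = np.asarray(z, float).ravel()
    if z.size != coupling.n_z:
        raise ValueError(f"z has {z.size} entries, expected {coupling.n_z}")
    St = coupling.free_selector
    S = coupling.constrained_selector
    x = St.T @ z[: coupling.n_free_soft_dofs]
    x += S.T @ (coupling.linear_map @ z + coupling.offset)
    return x


def coupling_residual(coupling: CouplingSystem, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """C(x) = S x - A z - c (zero for reconstructed states)."""
    return (
        coupling.constrained_selector @ np.asarray(x, float).ravel()
        - coupling.linear_map @ np.asarray(z, float).ravel()
        - coupling.offset
    )
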