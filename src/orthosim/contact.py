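"""Sliding contact as a quadratic penalty on signed penetration.

Each penetrating soft-tissue surface vertex p, against an obstacle with
witness point x_q and outward normal u, contributes a one-sided
non-penetration constraint u^T (x_p - x_q) = 0.  Stacking the point
differences as B x + d and the normals as columns of U, the penalty
energy with a uniform stiffness k is

    V_contact(x) = 1/2 k (U^T (B x + d))^T (U^T (B x + d)),

a true quadratic in x once the contact set is frozen: gradient
k B^T U U^T (B x + d) and constant positive-semidefinite Hessian
k B^T U U^T B.  The contact set is refreshed at every Newton iteration
(penetrating vertices only -- an equality treatment would glue the
surfaces instead of letting them slide) and held fixed inside it.

Obstacles are queried through a voxelized signed distance field with
trilinear interpolation (default 1 mm resolution), rebuilt whenever a
prescribed fragment moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import (
    MeshValidationError,
    SurfaceMesh,
    closest_point_query,
    signed_distance_query,
)

__all__ = ["VoxelSDF", "ContactSet", "detect_contacts", "contact_energy"]


class VoxelSDF:
    """Signed distance field of a closed surface sampled on a regular grid.

    Values are exact signed closest-point distances at the grid nodes
    (negative inside); queries interpolate trilinearly, and gradients are
    the analytic gradient of the interpolant, normalized.
    """

    def __init__(self, surface: SurfaceMesh, resolution_mm: float = 1.0, margin: float = 3.0):
        if not surface.is_closed():
            raise MeshValidationError("contact obstacles must be closed surfaces")
        if resolution_mm <= 0:
            raise ValueError("resolution_mm must be positive")
        self.surface = surface
        self.h = float(resolution_mm)
        lo = surface.vertices.min(axis=0) - margin
        hi = surface.vertices.max(axis=0) + margin
        self.origin = lo
        self.shape = np.maximum(np.ceil((hi - lo) / self.h).astype(int) + 1, 2)
        axes = [lo[k] + self.h * np.arange(self.shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        self.values = signed_distance_query(pts, surface).reshape(self.shape)

    def _locate(self, points: np.ndarray):
        rel = (np.atleast_2d(points) - self.origin) / self.h
        idx = np.clip(np.floor(rel).astype(int), 0, np.array(self.shape) - 2)
        frac = np.clip(rel - idx, 0.0, 1.0)
        return idx, frac

    def _corners(self, idx: np.ndarray) -> np.ndarray:
        v = self.values
        i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
        return np.stack(
            [
                v[i, j, k], v[i + 1, j, k], v[i, j + 1, k], v[i + 1, j + 1, k],
                v[i, j, k + 1], v[i + 1, j, k + 1], v[i, j + 1, k + 1], v[i + 1, j + 1, k + 1],
            ],
            axis=1,
        )

    def query(self, points: np.ndarray) -> np.ndarray:
        idx, f = self._locate(points)
        c = self._corners(idx)
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        w = np.stack(
            [
                (1 - fx) * (1 - fy) * (1 - fz), fx * (1 - fy) * (1 - fz),
                (1 - fx) * fy * (1 - fz), fx * fy * (1 - fz),
                (1 - fx) * (1 - fy) * fz, fx * (1 - fy) * fz,
                (1 - fx) * fy * fz, fx * fy * fz,
            ],
            axis=1,
        )
        return np.einsum("pc,pc->p", w, c)

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """Unit outward gradient of the interpolated field."""
        idx, f = self._locate(points)
        c = self._corners(idx)
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        dx = (
            -(1 - fy) * (1 - fz) * c[:, 0] + (1 - fy) * (1 - fz) * c[:, 1]
            - fy * (1 - fz) * c[:, 2] + fy * (1 - fz) * c[:, 3]
            - (1 - fy) * fz * c[:, 4] + (1 - fy) * fz * c[:, 5]
            - fy * fz * c[:, 6] + fy * fz * c[:, 7]
        )
        dy = (
            -(1 - fx) * (1 - fz) * c[:, 0] - fx * (1 - fz) * c[:, 1]
            + (1 - fx) * (1 - fz) * c[:, 2] + fx * (1 - fz) * c[:, 3]
            - (1 - fx) * fz * c[:, 4] - fx * fz * c[:, 5]
            + (1 - fx) * fz * c[:, 6] + fx * fz * c[:, 7]
        )
        dz = (
            -(1 - fx) * (1 - fy) * c[:, 0] - fx * (1 - fy) * c[:, 1]
            - (1 - fx) * fy * c[:, 2] - fx * fy * c[:, 3]
            + (1 - fx) * (1 - fy) * c[:, 4] + fx * (1 - fy) * c[:, 5]
            + (1 - fx) * fy * c[:, 6] + fx * fy * c[:, 7]
        )
        g = np.column_stack([dx, dy, dz]) / self.h
        n = np.linalg.norm(g, axis=1)
        n = np.where(n < 1e-12, 1.0, n)
        return g / n[:, None]


@dataclass
class ContactSet:
    """Active penalty contacts frozen for one Newton iteration."""

    pairs: list[tuple[int, np.ndarray, np.ndarray]]  # (soft vertex, witness, normal)
    point_map: sp.csr_matrix  # B: stacks (x_p - x_q) from system DoFs
    offsets: np.ndarray  # d
    normal_matrix: sp.csr_matrix  # U: one unit column per contact
    stiffness: float  # k, uniform

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)


def _empty_contact_set(n_dofs: int, stiffness: float) -> ContactSet:
    return ContactSet(
        [], sp.csr_matrix((0, n_dofs)), np.zeros(0), sp.csr_matrix((0, 0)), stiffness
    )


def detect_contacts(
    positions: np.ndarray,
    surface_vertex_ids: np.ndarray,
    obstacles: list[VoxelSDF],
    stiffness: float = 1e4,
) -> ContactSet:
    """Detect penetrating soft surface vertices against rigid obstacles.

    ``positions`` is the full deformed node array (n, 3);
    ``surface_vertex_ids`` selects the soft boundary vertices to test.
    A vertex strictly inside an obstacle (signed distance < 0) produces
    one pair: witness = closest point on the obstacle surface, normal =
    outward SDF gradient at the vertex.
    """
    x = np.asarray(positions, float).reshape(-1, 3)
    n_dofs = 3 * len(x)
    ids = np.asarray(surface_vertex_ids, np.int64)
    pairs: list[tuple[int, np.ndarray, np.ndarray]] = []
    for sdf in obstacles:
        # cheap AABB prefilter before the field query
        lo = sdf.origin
        hi = sdf.origin + sdf.h * (np.array(sdf.shape) - 1)
        p = x[ids]
        inbox = np.all((p >= lo) & (p <= hi), axis=1)
        if not inbox.any():
            continue
        cand = ids[inbox]
        phi = sdf.query(x[cand])
        pen = phi < 0.0
        if not pen.any():
            continue
        pen_ids = cand[pen]
        normals = sdf.gradient(x[pen_ids])
        _, witness, _ = closest_point_query(x[pen_ids], sdf.surface)
        for v, q, u in zip(pen_ids, witness, normals):
            pairs.append((int(v), q, u))
    if not pairs:
        return _empty_contact_set(n_dofs, stiffness)

    nc = len(pairs)
    rows, cols, vals = [], [], []
    d = np.zeros(3 * nc)
    urows, ucols, uvals = [], [], []
    for c, (v, q, u) in enumerate(pairs):
        for i in range(3):
            rows.append(3 * c + i)
            cols.append(3 * v + i)
            vals.append(1.0)
            d[3 * c + i] = -q[i]
            urows.append(3 * c + i)
            ucols.append(c)
            uvals.append(u[i])
    B = sp.csr_matrix((vals, (rows, cols)), shape=(3 * nc, n_dofs))
    U = sp.csr_matrix((uvals, (urows, ucols)), shape=(3 * nc, nc))
    return ContactSet(pairs, B, d, U, stiffness)


def contact_energy(contacts: ContactSet, positions: np.ndarray):
    """Penalty energy, gradient and constant PSD Hessian at ``positions``.

    Returns ``(energy, gradient, hessian)``; all zero for an empty set.
    """
    x = np.asarray(positions, float).ravel()
    n_dofs = contacts.point_map.shape[1]
    if contacts.n_contacts == 0:
        return 0.0, np.zeros(n_dofs), sp.csr_matrix((n_dofs, n_dofs))
    k = contacts.stiffness
    B, d, U = contacts.point_map, contacts.offsets, contacts.normal_matrix
    c = U.T @ (B @ x + d)  # per-contact signed violation
    energy = 0.5 * k * float(c @ c)
    grad = k * (B.T @ (U @ c))
    BU = (U.T @ B).tocsr()  # (nc, n_dofs)
    hess = k * (BU.T @ BU)
    return energy, grad, hess
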