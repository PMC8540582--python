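"""Rigid bone fragments and substepped transform trajectories.

A fragment is parameterized by its center-of-mass position ``x_b`` and
rotation ``R_b``; inside a solve the rotation is reparameterized by an
incremental axis-angle ``theta_b`` in the tangent space, so the world
position of a material point X (given relative to the center of mass) is
the linearized map

    x = R_b X - (R_b X) x theta_b + x_b

which is exact at theta_b = 0 and first-order accurate otherwise.
Accepting the increment applies the exact exponential map and resets
theta_b to zero.  Bones are rigid, so they contribute no elastic energy;
they act on the tissue only through coupling constraints and contact.

In the planning setting fragments are *prescribed*: the planned transform
is split into substeps (10 by default) and the tissue is relaxed to
equilibrium at each substep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import SurfaceMesh, Transform

__all__ = [
    "RigidFragment",
    "TransformTrajectory",
    "surface_volume_centroid",
    "world_position",
    "accept_increment",
    "make_trajectory",
]


def surface_volume_centroid(surface: SurfaceMesh) -> tuple[float, np.ndarray]:
    """Volume and center of mass of a closed surface, assuming uniform
    density (divergence-theorem integrals over origin-anchored tets)."""
    t = surface.triangles()
    dets = np.linalg.det(t)  # 6 * signed volume of (0, v0, v1, v2)
    vol = dets.sum() / 6.0
    if abs(vol) < 1e-12:
        raise ValueError("surface encloses no volume; cannot place a center of mass")
    centroids = t.sum(axis=1) / 4.0  # tet centroid (origin contributes 0)
    com = (dets[:, None] * centroids).sum(axis=0) / 6.0 / vol
    return float(vol), com


@dataclass
class RigidFragment:
    """A rigid bone fragment with its rest surface and current pose."""

    id: str
    surface: SurfaceMesh
    center_of_mass: np.ndarray | None = None  # current x_b (world, mm)
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    incremental_rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    prescribed: bool = True
    target_transform: Transform | None = None
    rest_center_of_mass: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.center_of_mass is None:
            if self.surface.is_closed():
                _, com = surface_volume_centroid(self.surface)
            else:
                # open fragment surface (e.g. produced by a planar cut that
                # was not capped): fall back to the area centroid
                areas = self.surface.face_areas()
                com = (areas[:, None] * self.surface.face_centroids()).sum(0) / areas.sum()
            self.center_of_mass = com
        self.center_of_mass = np.asarray(self.center_of_mass, float).reshape(3)
        if self.rest_center_of_mass is None:
            self.rest_center_of_mass = self.center_of_mass.copy()
        self.rest_center_of_mass = np.asarray(self.rest_center_of_mass, float).reshape(3)
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.incremental_rotation = np.asarray(self.incremental_rotation, float).reshape(3)
        self._check_rotation()

    def _check_rotation(self) -> None:
        R = self.rotation
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(R) - 1) > 1e-9:
            raise ValueError(f"fragment {self.id!r}: rotation is not a proper rotation")

    # -- pose handling -----------------------------------------------------

    def rest_relative(self, X_world: np.ndarray) -> np.ndarray:
        """Rest-frame coordinates of world rest points, relative to the COM."""
        return np.asarray(X_world, float) - self.rest_center_of_mass

    def set_pose(self, transform: Transform) -> None:
        """Place the fragment so its rest geometry maps through ``transform``
        (a world-frame rigid map applied to rest coordinates)."""
        self.rotation = transform.rotation.copy()
        self.center_of_mass = transform.apply(self.rest_center_of_mass)
        self.incremental_rotation = np.zeros(3)

    def pose_transform(self) -> Transform:
        """World transform of rest coordinates implied by the current pose
        (with theta_b = 0)."""
        t = self.center_of_mass - self.rotation @ self.rest_center_of_mass
        return Transform(self.rotation, t)

    def surface_at_pose(self) -> SurfaceMesh:
        return self.surface.transformed(self.pose_transform())


def world_position(X: np.ndarray, fragment: RigidFragment) -> np.ndarray:
    """Linearized world position of rest points X (relative to the COM)."""
    X = np.asarray(X, float)
    single = X.ndim == 1
    Xb = np.atleast_2d(X)
    rx = Xb @ fragment.rotation.T
    out = rx - np.cross(rx, np.broadcast_to(fragment.incremental_rotation, rx.shape))
    out = out + fragment.center_of_mass
    return out[0] if single else out


def accept_increment(fragment: RigidFragment) -> RigidFragment:
    """Fold theta_b into R_b with the exact exponential map, re-project to
    the rotation group by polar decomposition, and reset theta_b."""
    dR = Rotation.from_rotvec(fragment.incremental_rotation).as_matrix()
    R = dR @ fragment.rotation
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:  # reflection guard (never triggered by exp-map input)
        U[:, -1] *= -1.0
        R = U @ Vt
    fragment.rotation = R
    fragment.incremental_rotation = np.zeros(3)
    return fragment


@dataclass
class TransformTrajectory:
    """Substepped interpolation of one fragment's planned transform."""

    fragment_id: str
    substep_transforms: list[Transform]

    def __len__(self) -> int:
        return len(self.substep_transforms)


def make_trajectory(
    fragment: RigidFragment, target: Transform, substeps: int = 10
) -> TransformTrajectory:
    """Split ``target`` into ``substeps`` geodesic increments: the rotation
    axis-angle and the translation are both scaled by k/substeps, so every
    intermediate transform is a valid rigid transform and the last entry
    reproduces the target."""
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    rotvec = target.axis_angle()
    steps = []
    for k in range(1, substeps + 1):
        s = k / substeps
        steps.append(
            Transform(
                Rotation.from_rotvec(s * rotvec).as_matrix(), s * target.translation
            )
        )
    # the endpoint must be the target bit-near; rebuild from the original
    steps[-1] = Transform(target.rotation.copy(), target.translation.copy())
    return TransformTrajectory(fragment.id, steps)
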