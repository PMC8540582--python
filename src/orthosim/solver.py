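"""Reduced Newton solver for the quasistatic constrained equilibrium.

Each substep poses   min_x  V_soft(x) + V_contact(x)   subject to the
coupling constraints S x = A z + c.  Substituting the reconstruction
x = S~^T z + S^T (A z + c) turns the constrained quadratic model of every
Newton iteration into an unconstrained linear solve in the free DoFs z:

    (S~ + A^T S) H (S~^T + S^T A) z = -(S~ + A^T S) (g + H S^T c)

followed by a backtracking Armijo line search on the true energy, which
treats non-evaluable states (inverted elements) as infinite.  Constraints
are satisfied exactly at every iterate by construction.

Prescribed bone transforms are split into substeps (10 by default); each
substep updates the coupling offsets c and the obstacle distance fields,
then solves to convergence warm-started from the previous substep.
The solver is deterministic: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import contact as _contact
from .coupling import CouplingSystem, reconstruct_full_dofs
from .fem import Material, NonEvaluableState, assemble_energy
from .geometry import SurfaceMesh, TetMesh
from .rigid import RigidFragment, TransformTrajectory

__all__ = [
    "SolverSettings",
    "NewtonState",
    "SolverStagnation",
    "ElasticModel",
    "Scene",
    "reduce_system",
    "newton_solve",
    "run_plan",
]


@dataclass
class SolverSettings:
    """Newton/substepping controls.

    ``grad_tol`` is tested against the infinity norm of the reduced
    gradient (kPa*mm^2), scaled by the model's characteristic energy so
    behavior is mesh-size independent.
    """

    substeps: int = 10
    max_newton_per_substep: int = 50
    grad_tol: float = 1e-6
    line_search_shrink: float = 0.5
    armijo_c: float = 1e-4

    def __post_init__(self) -> None:
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if not 0.0 < self.line_search_shrink < 1.0:
            raise ValueError("line_search_shrink must lie in (0, 1)")
        if not 0.0 < self.armijo_c < 0.5:
            raise ValueError("armijo_c must lie in (0, 0.5)")


@dataclass
class NewtonState:
    iterate: np.ndarray
    free_vector: np.ndarray
    reduced_gradient: np.ndarray
    reduced_hessian: sp.csr_matrix | None
    energy: float
    iteration: int
    step_length: float
    converged: bool
    history: list[dict] = field(default_factory=list)


class SolverStagnation(RuntimeError):
    """Line search could not reduce the energy."""

    def __init__(self, message: str, state: NewtonState):
        super().__init__(message)
        self.state = state


# --------------------------------------------------------------------------
# Energy models
# --------------------------------------------------------------------------


class ElasticModel:
    """Neo-Hookean tissue energy plus (optional) penalty contact.

    ``begin_iteration`` refreshes the contact set at the current iterate;
    within the iteration (and its line search) the set stays frozen so the
    contact energy is a true quadratic.
    """

    def __init__(
        self,
        mesh: TetMesh,
        material: Material,
        f_ext: np.ndarray | None = None,
        obstacles: list["_contact.VoxelSDF"] | None = None,
        contact_stiffness: float = 1e4,
        contact_vertex_ids: np.ndarray | None = None,
        spd_project: bool = True,
    ):
        self.mesh = mesh
        self.material = material
        self.f_ext = f_ext
        self.obstacles = obstacles or []
        self.contact_stiffness = contact_stiffness
        if contact_vertex_ids is None:
            contact_vertex_ids = mesh.boundary_surface.used_vertices()
        self.contact_vertex_ids = contact_vertex_ids
        self.spd_project = spd_project
        self._contacts = None
        mean_vol = float(np.mean(mesh.quadrature_weights))
        self.energy_scale = material.young_modulus * mean_vol ** (2.0 / 3.0)

    def begin_iteration(self, x: np.ndarray) -> None:
        if self.obstacles:
            self._contacts = _contact.detect_contacts(
                np.asarray(x, float).reshape(-1, 3),
                self.contact_vertex_ids,
                self.obstacles,
                self.contact_stiffness,
            )

    def evaluate(self, x: np.ndarray, with_hessian: bool = True):
        sysen = assemble_energy(
            self.mesh, self.material, x, self.f_ext,
            with_hessian=with_hessian, spd_project=self.spd_project,
        )
        V, g, H = sysen.total_energy, sysen.gradient, sysen.hessian
        if self._contacts is not None and self._contacts.n_contacts:
            Vc, gc, Hc = _contact.contact_energy(self._contacts, x)
            V += Vc
            g = g + gc
            if with_hessian:
                H = (H + Hc).tocsr()
        return V, g, H


class QuadraticModel:
    """Explicit quadratic 1/2 x^T H x + g^T x (+const) -- a linear-FEM
    stand-in used to exercise the solver (Newton must converge in one
    step)."""

    def __init__(self, H, g, const: float = 0.0, energy_scale: float = 1.0):
        self.H = sp.csr_matrix(H)
        self.g0 = np.asarray(g, float).ravel()
        self.const = const
        self.energy_scale = energy_scale

    def begin_iteration(self, x) -> None:
        pass

    def evaluate(self, x, with_hessian: bool = True):
        x = np.asarray(x, float).ravel()
        V = 0.5 * float(x @ (self.H @ x)) + float(self.g0 @ x) + self.const
        g = self.H @ x + self.g0
        return V, g, (self.H if with_hessian else None)


# --------------------------------------------------------------------------
# Constraint elimination
# --------------------------------------------------------------------------


def reduce_system(H: sp.spmatrix, g: np.ndarray, coupling: CouplingSystem):
    """Eliminate the coupling constraints from the quadratic model
    1/2 x^T H x + g^T x,  S x = A z + c.

    Returns the sparse reduced matrix (S~ + A^T S) H (S~^T + S^T A) and
    right-hand side -(S~ + A^T S)(g + H S^T c); solving them yields the
    minimizing free vector z.
    """
    H = sp.csr_matrix(H)
    g = np.asarray(g, float).ravel()
    if H.shape[0] != 3 * coupling.n_nodes or g.size != H.shape[0]:
        raise ValueError(
            f"H/g of dimension {H.shape[0]}/{g.size}, coupling expects {3 * coupling.n_nodes}"
        )
    J = coupling.jacobian()
    Sc = coupling.constrained_selector.T @ coupling.offset
    M = (J.T @ H @ J).tocsr()
    rhs = -J.T @ (g + H @ Sc)
    if coupling.free_fragment_ids:
        # unloaded free fragments are indeterminate without regularization
        reg = 1e-8 * (abs(M.diagonal()).max() + 1.0)
        nr = 6 * len(coupling.free_fragment_ids)
        idx = np.arange(M.shape[0] - nr, M.shape[0])
        M = (M + sp.coo_matrix((np.full(nr, reg), (idx, idx)), shape=M.shape)).tocsr()
    return M, rhs


def _solve_sparse(M: sp.spmatrix, rhs: np.ndarray) -> np.ndarray:
    if M.shape[0] == 0:
        return np.zeros(0)
    try:
        return spla.splu(sp.csc_matrix(M)).solve(rhs)
    except RuntimeError:
        # singular factor: fall back with a tiny diagonal shift
        reg = 1e-10 * (abs(M.diagonal()).max() + 1.0)
        return spla.splu(sp.csc_matrix(M) + reg * sp.eye(M.shape[0], format="csc")).solve(rhs)


# --------------------------------------------------------------------------
# Newton iteration
# --------------------------------------------------------------------------


def newton_solve(
    model,
    coupling: CouplingSystem,
    settings: SolverSettings,
    z0: np.ndarray | None = None,
) -> NewtonState:
    """Minimize the model energy over the free DoFs z.

    The initial iterate is reconstructed from ``z0`` (zeros if omitted) so
    it satisfies the couplings exactly.  Terminates when the reduced
    gradient infinity norm drops below grad_tol * (1 + |V| / scale) or the
    iteration cap is reached; accepted steps must pass an Armijo
    backtracking line search, with non-evaluable energies treated as
    infinite.
    """
    z = np.zeros(coupling.n_z) if z0 is None else np.asarray(z0, float).copy()
    x = reconstruct_full_dofs(coupling, z)
    history: list[dict] = []
    scale = getattr(model, "energy_scale", 1.0)
    step_length = 0.0
    rg = np.zeros(coupling.n_z)
    M = None
    V = np.inf

    for it in range(settings.max_newton_per_substep + 1):
        model.begin_iteration(x)
        V, g, H = model.evaluate(x, with_hessian=True)
        J = coupling.jacobian()
        rg = J.T @ g
        tol_eff = settings.grad_tol * (1.0 + abs(V) / scale)
        converged = (rg.size == 0) or (np.linalg.norm(rg, np.inf) <= tol_eff)
        if converged or it == settings.max_newton_per_substep:
            return NewtonState(x, z, rg, M, V, it, step_length, converged, history)

        M, rhs = reduce_system(H, g - H @ x, coupling)
        z_new = _solve_sparse(M, rhs)
        dz = z_new - z
        slope = float(rg @ dz)
        if slope > 0.0:  # safeguard: fall back to scaled steepest descent
            gmax = np.linalg.norm(rg, np.inf)
            dz = -rg / gmax  # first trial moves at most 1 mm per DoF
            slope = float(rg @ dz)

        alpha = 1.0
        accepted = False
        while alpha > 1e-12:
            z_try = z + alpha * dz
            x_try = reconstruct_full_dofs(coupling, z_try)
            try:
                V_try, _, _ = model.evaluate(x_try, with_hessian=False)
            except NonEvaluableState:
                V_try = np.inf
            if V_try <= V + settings.armijo_c * alpha * slope + 1e-14 * (1.0 + abs(V)):
                accepted = True
                break
            alpha *= settings.line_search_shrink
        if not accepted:
            state = NewtonState(x, z, rg, M, V, it, alpha, False, history)
            raise SolverStagnation(
                f"line search stagnated at iteration {it}: energy {V:.6e}, "
                f"|reduced grad|_inf {np.linalg.norm(rg, np.inf):.3e}, "
                f"step below 1e-12",
                state,
            )
        z = z + alpha * dz
        x = reconstruct_full_dofs(coupling, z)
        step_length = alpha
        history.append(
            {
                "iteration": it,
                "energy": V,
                "grad_norm": float(np.linalg.norm(rg, np.inf)),
                "step_length": alpha,
            }
        )
    raise AssertionError("unreachable")


# --------------------------------------------------------------------------
# Scene and substepping driver
# --------------------------------------------------------------------------


@dataclass
class Scene:
    """Everything one simulation needs: tissue mesh, material, fragments,
    coupling system and contact configuration."""

    mesh: TetMesh
    material: Material
    fragments: dict[str, RigidFragment]
    coupling: CouplingSystem
    interface: SurfaceMesh | None = None
    assignment: object | None = None  # FaceGroupAssignment of the interface
    weight_field: object | None = None  # WeightField used to build the coupling
    fixed_nodes: np.ndarray | None = None
    contact_fragment_ids: list[str] = field(default_factory=list)
    contact_stiffness: float = 1e4
    sdf_resolution_mm: float = 1.0
    f_ext: np.ndarray | None = None


def run_plan(
    scene: Scene,
    trajectories: list[TransformTrajectory],
    settings: SolverSettings | None = None,
) -> tuple[TetMesh, list[dict]]:
    """Drive the prescribed fragments along their substepped trajectories,
    solving the tissue to equilibrium at every substep (warm-started).

    Returns the deformed mesh and a per-iteration log with columns
    substep, iteration, energy, grad_norm, step_length.
    """
    settings = settings or SolverSettings()
    traj_by_id = {t.fragment_id: t for t in trajectories}
    for fid in traj_by_id:
        if fid not in scene.fragments:
            raise ValueError(f"trajectory names unknown fragment {fid!r}")
    n_sub = max((len(t) for t in trajectories), default=settings.substeps)

    z = scene.coupling.initial_z(scene.mesh.rest_positions, scene.fragments)
    log: list[dict] = []
    x = scene.mesh.rest_positions.ravel().copy()

    for s in range(n_sub):
        for fid, frag in scene.fragments.items():
            if frag.prescribed and fid in traj_by_id:
                frag.set_pose(traj_by_id[fid].substep_transforms[min(s, len(traj_by_id[fid]) - 1)])
        scene.coupling.update_offsets(scene.fragments)

        obstacles = []
        for fid in scene.contact_fragment_ids:
            frag = scene.fragments[fid]
            obstacles.append(
                _contact.VoxelSDF(frag.surface_at_pose(), scene.sdf_resolution_mm)
            )
        model = ElasticModel(
            scene.mesh,
            scene.material,
            scene.f_ext,
            obstacles=obstacles,
            contact_stiffness=scene.contact_stiffness,
        )
        try:
            state = newton_solve(model, scene.coupling, settings, z0=z)
        except SolverStagnation as exc:
            for row in exc.state.history:
                log.append({"substep": s, **row})
            raise SolverStagnation(
                f"substep {s}: {exc}", exc.state
            ) from exc
        z = state.free_vector
        x = state.iterate
        for row in state.history:
            log.append({"substep": s, **row})
        log.append(
            {
                "substep": s,
                "iteration": state.iteration,
                "energy": state.energy,
                "grad_norm": float(np.linalg.norm(state.reduced_gradient, np.inf))
                if state.reduced_gradient.size
                else 0.0,
                "step_length": state.step_length,
            }
        )
    return scene.mesh.with_positions(x.reshape(-1, 3)), log
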