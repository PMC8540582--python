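"""Neo-Hookean soft-tissue finite elements.

The soft tissue is one homogeneous elastic continuum discretized with
linear tetrahedra and one integration point per element.  The energy
density is the compressible Neo-Hookean form

    psi(F) = mu/2 (tr(F^T F) - 3) - mu log det F + lambda/2 (log det F)^2

with Lame constants derived from Young modulus E (kPa) and Poisson ratio
nu.  Energies are kPa*mm^3 (microjoules), so external forces live in
kPa*mm^2.  Gravity is deliberately ignored: the tissue is imaged in a
gravity-loaded rest state, and adding gravity on top of that state would
deform it away from the scan.

The log-det barrier is undefined for inverted elements; evaluation there
raises :class:`NonEvaluableState`, which the solver's line search treats
as infinite energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import TetMesh

__all__ = [
    "Material",
    "NonEvaluableState",
    "SystemEnergy",
    "deformation_gradients",
    "deformation_gradient",
    "energy_density",
    "first_pk_stress",
    "stress_derivative",
    "assemble_energy",
]


class NonEvaluableState(ArithmeticError):
    """det F <= 0 somewhere: the energy is not defined at this state."""

    def __init__(self, elements, dets):
        self.elements = np.atleast_1d(elements)
        self.dets = np.atleast_1d(dets)
        super().__init__(
            f"non-evaluable deformation state: det F <= 0 in elements "
            f"{self.elements.tolist()} (det F = {self.dets.tolist()})"
        )


@dataclass
class Material:
    """Isotropic Neo-Hookean material (kPa).

    Defaults are the facial soft-tissue values used throughout this
    package: E = 100 kPa, nu = 0.47 (nearly incompressible).
    """

    young_modulus: float = 100.0
    poisson_ratio: float = 0.47

    def __post_init__(self) -> None:
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in the open interval (0, 0.5)")
        if self.young_modulus <= 0.0:
            raise ValueError("young_modulus must be positive")

    @property
    def mu(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def lam(self) -> float:
        e, nu = self.young_modulus, self.poisson_ratio
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))


@dataclass
class SystemEnergy:
    """Assembled total energy, gradient and (optionally) Hessian.

    ``gradient`` is d(total)/dx over all soft DoFs; the internal elastic
    forces are minus the elastic part of this gradient.
    """

    total_energy: float
    gradient: np.ndarray
    hessian: sp.csr_matrix | None = None
    external_forces: np.ndarray | None = None


# -- constitutive model ------------------------------------------------------


def _as_batch(F: np.ndarray) -> tuple[np.ndarray, bool]:
    F = np.asarray(F, float)
    if F.ndim == 2:
        return F[None], True
    return F, False


def _check_dets(J: np.ndarray) -> None:
    bad = J <= 0.0
    if bad.any():
        raise NonEvaluableState(np.where(bad)[0], J[bad])


def energy_density(F: np.ndarray, material: Material):
    """psi(F) in kPa; accepts a single 3x3 or a batch (m, 3, 3)."""
    Fb, single = _as_batch(F)
    J = np.linalg.det(Fb)
    _check_dets(J)
    logj = np.log(J)
    mu, lam = material.mu, material.lam
    i1 = np.einsum("mij,mij->m", Fb, Fb)
    psi = 0.5 * mu * (i1 - 3.0) - mu * logj + 0.5 * lam * logj**2
    return float(psi[0]) if single else psi


def first_pk_stress(F: np.ndarray, material: Material):
    """First Piola-Kirchhoff stress P = dpsi/dF (kPa)."""
    Fb, single = _as_batch(F)
    J = np.linalg.det(Fb)
    _check_dets(J)
    logj = np.log(J)
    mu, lam = material.mu, material.lam
    finv_t = np.linalg.inv(Fb).transpose(0, 2, 1)
    P = mu * (Fb - finv_t) + lam * logj[:, None, None] * finv_t
    return P[0] if single else P


def stress_derivative(F: np.ndarray, material: Material):
    """d^2 psi / dF^2 as a symmetric 9x9 (row-major vec of F).

    Index layout: row 3*i + j corresponds to F_ij.
    """
    Fb, single = _as_batch(F)
    J = np.linalg.det(Fb)
    _check_dets(J)
    logj = np.log(J)
    mu, lam = material.mu, material.lam
    finv = np.linalg.inv(Fb)
    m = len(Fb)
    A = np.zeros((m, 3, 3, 3, 3))
    A += mu * np.einsum("ik,jl->ijkl", np.eye(3), np.eye(3))
    coef = mu - lam * logj
    A += coef[:, None, None, None, None] * np.einsum("mjk,mli->mijkl", finv, finv)
    A += lam * np.einsum("mji,mlk->mijkl", finv, finv)
    A = A.reshape(m, 9, 9)
    return A[0] if single else A


# -- discretization ----------------------------------------------------------


def deformation_gradients(mesh: TetMesh, positions: np.ndarray) -> np.ndarray:
    """Per-element deformation gradients F (m, 3, 3).

    ``positions`` is the full soft DoF vector (3n,) or an (n, 3) array.
    """
    x = np.asarray(positions, float).reshape(-1, 3)
    if len(x) != mesh.n_nodes:
        raise ValueError(f"positions for {len(x)} nodes, mesh has {mesh.n_nodes}")
    xe = x[mesh.tets]  # (m, 4, 3)
    # F_ij = sum_a x_{a,i} dN_a/dX_j
    return np.einsum("mai,maj->mij", xe, mesh.shape_gradients)


def deformation_gradient(mesh: TetMesh, element: int, positions: np.ndarray) -> np.ndarray:
    x = np.asarray(positions, float).reshape(-1, 3)
    xe = x[mesh.tets[element]]
    return np.einsum("ai,aj->ij", xe, mesh.shape_gradients[element])


def _project_spd(K: np.ndarray) -> np.ndarray:
    """Clamp eigenvalues of symmetric 12x12 element blocks to >= 0."""
    K = 0.5 * (K + K.transpose(0, 2, 1))
    w, V = np.linalg.eigh(K)
    w = np.maximum(w, 0.0)
    return np.einsum("mab,mb,mcb->mac", V, w, V)


def assemble_energy(
    mesh: TetMesh,
    material: Material,
    positions: np.ndarray,
    f_ext: np.ndarray | None = None,
    with_hessian: bool = True,
    spd_project: bool = True,
) -> SystemEnergy:
    """Assemble total energy sum_e w_e psi(F_e) - f_ext^T x, its gradient
    and, when requested, the sparse Hessian.

    ``spd_project`` eigen-projects each 12x12 element block to positive
    semidefinite before scattering, the standard guard that keeps the
    Newton model solvable under compression; disable it to obtain the
    exact second derivative (e.g. for finite-difference checks).
    """
    x = np.asarray(positions, float).ravel()
    n = mesh.n_nodes
    if x.size != 3 * n:
        raise ValueError(f"positions has {x.size} DoFs, expected {3 * n}")
    if f_ext is not None:
        f_ext = np.asarray(f_ext, float).ravel()
        if f_ext.size != 3 * n:
            raise ValueError("f_ext length mismatch")

    F = deformation_gradients(mesh, x)
    w = mesh.quadrature_weights
    psi = energy_density(F, material)  # raises NonEvaluableState on inversion
    total = float(np.dot(w, psi))
    P = first_pk_stress(F, material)

    G = mesh.shape_gradients  # (m, 4, 3)
    # elastic gradient at node a: w * P @ dN_a/dX
    ge = np.einsum("m,mij,maj->mai", w, P, G)  # (m, 4, 3)
    grad = np.zeros((n, 3))
    np.add.at(grad, mesh.tets, ge)
    grad = grad.ravel()
    if f_ext is not None:
        total -= float(np.dot(f_ext, x))
        grad = grad - f_ext

    hess = None
    if with_hessian:
        A = stress_derivative(F, material)  # (m, 9, 9)
        A5 = A.reshape(-1, 3, 3, 3, 3)
        K = np.einsum("m,mijkl,maj,mbl->maibk", w, A5, G, G).reshape(-1, 12, 12)
        if spd_project:
            K = _project_spd(K)
        gdof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
        rows = np.repeat(gdof, 12, axis=1).ravel()
        cols = np.tile(gdof, (1, 12)).ravel()
        hess = sp.coo_matrix((K.ravel(), (rows, cols)), shape=(3 * n, 3 * n)).tocsr()
        hess = 0.5 * (hess + hess.T)

    return SystemEnergy(total, grad, hess, f_ext)
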