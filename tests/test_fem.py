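"""Constitutive model and FEM assembly against independent oracles."""

import numpy as np
import pytest

from orthosim.fem import (
    Material,
    NonEvaluableState,
    assemble_energy,
    deformation_gradient,
    deformation_gradients,
    energy_density,
    first_pk_stress,
    stress_derivative,
)
from orthosim.geometry import Transform

from conftest import random_tet_mesh


class _UnitMaterial:
    mu = 1.0
    lam = 1.0


def test_material_lame_constants():
    m = Material(100.0, 0.47)
    np.testing.assert_allclose(m.mu, 100.0 / (2 * 1.47), rtol=1e-12)
    np.testing.assert_allclose(m.lam, 100.0 * 0.47 / (1.47 * 0.06), rtol=1e-12)
    with pytest.raises(ValueError):
        Material(100.0, 0.5)
    with pytest.raises(ValueError):
        Material(-1.0, 0.3)


def test_energy_zero_at_identity_and_any_rotation():
    mat = Material()
    assert energy_density(np.eye(3), mat) == 0.0
    R = Transform.from_axis_angle([0.4, -1.1, 0.2]).rotation
    assert abs(energy_density(R, mat)) < 1e-12
    assert np.abs(first_pk_stress(np.eye(3), mat)).max() < 1e-12


def test_energy_density_uniaxial_closed_form():
    F = np.diag([2.0, 1.0, 1.0])
    want = 1.5 - np.log(2.0) + 0.5 * np.log(2.0) ** 2
    np.testing.assert_allclose(energy_density(F, _UnitMaterial), want, rtol=1e-12)
    P = first_pk_stress(F, _UnitMaterial)
    np.testing.assert_allclose(
        P, np.diag([1.5 + 0.5 * np.log(2.0), np.log(2.0), np.log(2.0)]), rtol=1e-12
    )


def test_inverted_state_is_non_evaluable():
    with pytest.raises(NonEvaluableState):
        energy_density(np.diag([-1.0, 1.0, 1.0]), Material())


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_stress_matches_finite_differences_of_energy(seed):
    rng = np.random.default_rng(seed)
    mat = Material()
    F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
    if np.linalg.det(F) <= 0.1:
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
    P = first_pk_stress(F, mat)
    h = 1e-6
    fd = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            fd[i, j] = (energy_density(Fp, mat) - energy_density(Fm, mat)) / (2 * h)
    np.testing.assert_allclose(P, fd, rtol=1e-5, atol=1e-7 * np.abs(P).max())


def test_stress_derivative_symmetric_and_matches_fd():
    rng = np.random.default_rng(4)
    mat = Material(10.0, 0.3)
    F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
    A = stress_derivative(F, mat)
    np.testing.assert_allclose(A, A.T, atol=1e-12 * np.abs(A).max())
    h = 1e-6
    fd = np.zeros((9, 9))
    for k in range(3):
        for ll in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[k, ll] += h
            Fm[k, ll] -= h
            fd[:, 3 * k + ll] = (
                first_pk_stress(Fp, mat) - first_pk_stress(Fm, mat)
            ).ravel() / (2 * h)
    np.testing.assert_allclose(A, fd, rtol=1e-5, atol=1e-6 * np.abs(A).max())


def test_deformation_gradient_identity_scaling_translation(unit_tet):
    X = unit_tet.rest_positions
    np.testing.assert_allclose(deformation_gradient(unit_tet, 0, X), np.eye(3), atol=1e-14)
    np.testing.assert_allclose(
        deformation_gradient(unit_tet, 0, 2.0 * X), 2.0 * np.eye(3), atol=1e-14
    )
    np.testing.assert_allclose(
        deformation_gradient(unit_tet, 0, X + np.array([3.0, -1.0, 2.0])),
        np.eye(3), atol=1e-14,
    )


def test_assemble_rest_state_zero(unit_tet):
    se = assemble_energy(unit_tet, Material(), unit_tet.rest_positions.ravel())
    assert se.total_energy == 0.0
    assert np.abs(se.gradient).max() == 0.0


def test_frame_invariance_of_total_energy():
    mesh = random_tet_mesh(seed=9)
    mat = Material()
    rng = np.random.default_rng(2)
    x = mesh.rest_positions + 0.05 * rng.standard_normal(mesh.rest_positions.shape)
    e0 = assemble_energy(mesh, mat, x.ravel(), with_hessian=False).total_energy
    T = Transform.from_axis_angle([1.0, 0.4, -0.3], [7.0, -2.0, 3.0])
    e1 = assemble_energy(mesh, mat, T.apply(x).ravel(), with_hessian=False).total_energy
    scale = mat.young_modulus * mesh.total_volume()
    assert abs(e1 - e0) <= 1e-9 * scale
    # rigid motion of the rest state itself costs nothing
    e2 = assemble_energy(
        mesh, mat, T.apply(mesh.rest_positions).ravel(), with_hessian=False
    ).total_energy
    assert abs(e2) <= 1e-10 * scale


def test_assembled_gradient_and_hessian_match_fd():
    mesh = random_tet_mesh(seed=3)
    mat = Material()
    rng = np.random.default_rng(8)
    x = (mesh.rest_positions + 0.02 * rng.standard_normal(mesh.rest_positions.shape)).ravel()
    se = assemble_energy(mesh, mat, x, spd_project=False)
    h = 1e-6
    n = x.size
    fd_g = np.zeros(n)
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fd_g[i] = (
            assemble_energy(mesh, mat, xp, with_hessian=False).total_energy
            - assemble_energy(mesh, mat, xm, with_hessian=False).total_energy
        ) / (2 * h)
    denom = np.linalg.norm(se.gradient)
    assert np.linalg.norm(se.gradient - fd_g) / denom <= 1e-5

    H = se.hessian.toarray()
    fd_H = np.zeros((n, n))
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        gp = assemble_energy(mesh, mat, xp, with_hessian=False, spd_project=False).gradient
        gm = assemble_energy(mesh, mat, xm, with_hessian=False, spd_project=False).gradient
        fd_H[:, i] = (gp - gm) / (2 * h)
    assert np.linalg.norm(H - fd_H) / np.linalg.norm(H) <= 1e-4
    # symmetry of the assembled matrix
    assert np.abs(H - H.T).max() <= 1e-9 * np.abs(H).max()


def test_small_strain_uniaxial_modulus():
    mat = Material()
    eps = 1e-5
    P = first_pk_stress(np.diag([1.0 + eps, 1.0, 1.0]), mat)
    np.testing.assert_allclose(P[0, 0] / eps, 2 * mat.mu + mat.lam, rtol=1e-3)


def test_energy_nonnegative_near_identity():
    rng = np.random.default_rng(12)
    mat = Material()
    G = rng.standard_normal((1000, 3, 3))
    F = np.eye(3) + 1e-3 * G
    psi = energy_density(F, mat)
    assert np.all(psi >= 0.0)


def _linear_stiffness_oracle(mesh, mat):
    """Independent small-strain stiffness: K = sum_e V_e B_e^T C B_e with
    the standard isotropic 6x6 elasticity matrix (Voigt notation)."""
    lam, mu = mat.lam, mat.mu
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = mu * np.eye(3)
    n = mesh.n_nodes
    K = np.zeros((3 * n, 3 * n))
    for e in range(mesh.n_elements):
        G = mesh.shape_gradients[e]  # (4, 3)
        B = np.zeros((6, 12))
        for a in range(4):
            bx, by, bz = G[a]
            B[:, 3 * a : 3 * a + 3] = [
                [bx, 0, 0], [0, by, 0], [0, 0, bz],
                [by, bx, 0], [0, bz, by], [bz, 0, bx],
            ]
        Ke = mesh.quadrature_weights[e] * B.T @ C @ B
        dofs = (3 * mesh.tets[e][:, None] + np.arange(3)).ravel()
        K[np.ix_(dofs, dofs)] += Ke
    return K


def test_rest_hessian_equals_linear_elastic_stiffness():
    # 2-tet mesh sharing a face
    X = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], float
    )
    from orthosim.geometry import TetMesh

    mesh = TetMesh(X, [[0, 1, 2, 3], [1, 2, 3, 4]])
    mat = Material()
    H = assemble_energy(
        mesh, mat, mesh.rest_positions.ravel(), spd_project=False
    ).hessian.toarray()
    K = _linear_stiffness_oracle(mesh, mat)
    assert np.abs(H - K).max() <= 1e-6 * np.abs(K).max()


def test_batched_deformation_gradients_agree_with_single():
    mesh = random_tet_mesh(seed=6)
    rng = np.random.default_rng(1)
    x = mesh.rest_positions + 0.1 * rng.standard_normal(mesh.rest_positions.shape)
    F = deformation_gradients(mesh, x)
    for e in (0, mesh.n_elements // 2, mesh.n_elements - 1):
        np.testing.assert_allclose(F[e], deformation_gradient(mesh, e, x), atol=1e-14)
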