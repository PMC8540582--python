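"""Constraint elimination, Newton iteration, and the substepping driver."""

import numpy as np
import pytest
import scipy.sparse as sp

from orthosim.coupling import WeightField, build_coupling, coupling_residual
from orthosim.fem import Material
from orthosim.fixtures import FixtureSpec, make_advance_plan, make_slab_scene
from orthosim.geometry import Transform
from orthosim.rigid import RigidFragment
from orthosim.solver import (
    ElasticModel,
    QuadraticModel,
    Scene,
    SolverSettings,
    newton_solve,
    reduce_system,
    run_plan,
)

from conftest import box_surface, random_tet_mesh


def test_reduce_empty_coupling_returns_full_system():
    mesh = random_tet_mesh(seed=1)
    n = 3 * mesh.n_nodes
    cpl = build_coupling(mesh, [], None, [])
    rng = np.random.default_rng(0)
    H = sp.random(n, n, density=0.05, random_state=0)
    H = (H + H.T).tocsr()
    g = rng.standard_normal(n)
    M, rhs = reduce_system(H, g, cpl)
    np.testing.assert_allclose(M.toarray(), H.toarray(), atol=1e-14)
    np.testing.assert_allclose(rhs, -g, atol=1e-14)


def test_reduce_everything_fixed_zero_dimensional():
    mesh = random_tet_mesh(seed=1)
    cpl = build_coupling(mesh, np.arange(mesh.n_nodes), None, [])
    n = 3 * mesh.n_nodes
    H = sp.eye(n, format="csr")
    M, rhs = reduce_system(H, np.ones(n), cpl)
    assert M.shape == (0, 0) and rhs.size == 0


def _kkt_oracle(H, g, cpl):
    """Dense Lagrange-multiplier solve of the same constrained quadratic
    (including the solver's rigid Tikhonov regularization)."""
    N = H.shape[0]
    nz = cpl.n_z
    nfs = cpl.n_free_soft_dofs
    nr = nz - nfs
    S = cpl.constrained_selector.toarray()
    St = cpl.free_selector.toarray()
    A = cpl.linear_map.toarray()
    As, Ar = A[:, :nfs], A[:, nfs:]
    Hh = np.zeros((N + nr, N + nr))
    Hh[:N, :N] = H.toarray()
    if nr:
        # same Tikhonov term the reduced path adds to the rigid block
        J = cpl.jacobian()
        M_noreg = (J.T @ H @ J).toarray()
        reg = 1e-8 * (np.abs(np.diag(M_noreg)).max() + 1.0)
        Hh[N:, N:] = reg * np.eye(nr)
    gh = np.concatenate([g, np.zeros(nr)])
    C = np.zeros((S.shape[0], N + nr))
    C[:, :N] = S - As @ St
    C[:, N:] = -Ar
    KKT = np.block([[Hh, C.T], [C, np.zeros((C.shape[0], C.shape[0]))]])
    sol = np.linalg.solve(KKT, np.concatenate([-gh, cpl.offset]))
    return np.concatenate([St @ sol[:N], sol[N : N + nr]])


@pytest.mark.parametrize("seed", range(20))
def test_reduced_solve_equals_kkt_oracle(seed):
    """Mixed fixed/bonded/LBS/free-fragment instances: eliminating the
    constraints gives the same minimizer as Lagrange multipliers."""
    rng = np.random.default_rng(seed)
    mesh = random_tet_mesh(seed=seed % 5, n_points=14)
    n = mesh.n_nodes
    nodes = rng.permutation(n)
    fixed = np.sort(nodes[:3])
    coupled = np.sort(nodes[3 : 3 + 4])
    fragA = RigidFragment("a", box_surface([0, 0, 0], [2, 2, 2]),
                          prescribed=bool(seed % 2))
    fragB = RigidFragment("b", box_surface([5, 5, 5], [8, 8, 8]))
    fragB.set_pose(Transform.from_axis_angle([0.1, 0.2, -0.1], [1.0, -2.0, 0.5]))
    wf = WeightField(
        coupled,
        [["a"], ["a", "b"], ["b", "a"], ["b"]],
        [[1.0], [0.7, 0.3], [0.55, 0.45], [1.0]],
    )
    cpl = build_coupling(mesh, fixed, wf, [fragA, fragB])
    N = 3 * n
    M0 = rng.standard_normal((N, N))
    H = sp.csr_matrix(M0 @ M0.T + N * np.eye(N))
    g = rng.standard_normal(N)
    M, rhs = reduce_system(H, g, cpl)
    z = np.linalg.solve(M.toarray(), rhs)
    z_kkt = _kkt_oracle(H, g, cpl)
    assert np.abs(z - z_kkt).max() <= 1e-8


def test_newton_converges_in_zero_iterations_at_minimum():
    n = 12
    model = QuadraticModel(sp.eye(n, format="csr"), np.zeros(n))
    cpl = build_coupling(_tiny_mesh(n // 3), [], None, [])
    state = newton_solve(model, cpl, SolverSettings())
    assert state.iteration == 0 and state.converged


def _tiny_mesh(n_nodes):
    """A placeholder mesh with the requested node count (coupling only
    needs the DoF dimension)."""
    rng = np.random.default_rng(0)
    from orthosim.geometry import TetMesh

    while True:
        pts = rng.uniform(0, 1, (max(n_nodes, 4), 3))
        try:
            return TetMesh(pts[:n_nodes], [[0, 1, 2, 3]])
        except Exception:
            continue


def test_newton_on_quadratic_takes_exactly_one_iteration():
    rng = np.random.default_rng(5)
    n = 12
    M0 = rng.standard_normal((n, n))
    H = sp.csr_matrix(M0 @ M0.T + n * np.eye(n))
    g = rng.standard_normal(n)
    model = QuadraticModel(H, g)
    cpl = build_coupling(_tiny_mesh(n // 3), [], None, [])
    state = newton_solve(model, cpl, SolverSettings())
    assert state.iteration == 1 and state.converged
    np.testing.assert_allclose(state.iterate, np.linalg.solve(H.toarray(), -g),
                               atol=1e-9)


def test_energy_monotonically_decreases(cut_slab_scene):
    sc = cut_slab_scene
    plans = make_advance_plan(sc, "block0_1", advance_mm=(4.0, 0.0, 0.0), substeps=5)
    _, log = run_plan(sc, plans, SolverSettings(substeps=5))
    by_substep = {}
    for row in log:
        by_substep.setdefault(row["substep"], []).append(row["energy"])
    for energies in by_substep.values():
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-12 * (1.0 + np.abs(energies[:-1])))
    _reset(sc)


def test_fully_bonded_translation_reaches_exact_equilibrium():
    """Bonding the slab's entire boundary to a translated fragment must
    reproduce the translated rest pose: rigid motion costs no energy."""
    from orthosim.rigid import make_trajectory

    spec = FixtureSpec(slab_dimensions=[30.0, 20.0, 10.0], grid_resolution=(6, 4, 2),
                       fixed_region="none")
    sc = make_slab_scene(spec)
    mesh = sc.mesh
    frag = RigidFragment("shell", mesh.boundary_surface)
    boundary = mesh.boundary_surface.used_vertices()
    wf = WeightField(boundary, [["shell"]] * len(boundary), [[1.0]] * len(boundary))
    cpl = build_coupling(mesh, [], wf, [frag])
    scene = Scene(mesh=mesh, material=Material(), fragments={"shell": frag},
                  coupling=cpl)
    traj = make_trajectory(frag, Transform(np.eye(3), np.array([5.0, 0.0, 0.0])),
                           substeps=5)
    deformed, log = run_plan(scene, [traj], SolverSettings(substeps=5))
    assert log[-1]["energy"] <= 1e-10
    np.testing.assert_allclose(
        deformed.rest_positions, mesh.rest_positions + [5.0, 0.0, 0.0], atol=1e-6
    )


def test_constraints_hold_exactly_at_solution(cut_slab_scene):
    sc = cut_slab_scene
    plans = make_advance_plan(sc, "block0_1", advance_mm=(2.0, 0.0, 0.0), substeps=3)
    deformed, _ = run_plan(sc, plans, SolverSettings(substeps=3))
    z = sc.coupling.initial_z(deformed.rest_positions, sc.fragments)
    res = coupling_residual(sc.coupling, deformed.rest_positions.ravel(), z)
    assert np.abs(res).max() <= 1e-10
    _reset(sc)


def test_identity_plan_returns_rest_mesh(cut_slab_scene):
    sc = cut_slab_scene
    plans = make_advance_plan(sc, "block0_1", advance_mm=(0.0, 0.0, 0.0), substeps=3)
    deformed, _ = run_plan(sc, plans, SolverSettings(substeps=3))
    np.testing.assert_allclose(deformed.rest_positions, sc.mesh.rest_positions,
                               atol=1e-10)
    _reset(sc)


def test_substep_refinement_changes_little():
    """The quasistatic equilibrium is path independent: 10 vs 20 substeps
    land within 0.1 mm."""
    def run(substeps):
        spec = FixtureSpec(slab_dimensions=[60.0, 20.0, 20.0], grid_resolution=(12, 4, 4),
                           bone_blocks=[([15.0, 5.0, 5.0], [45.0, 15.0, 10.0])],
                           cut_planes=[[([30.0, 10.0, 7.5], [1.0, 0.0, 0.0])]],
                           fixed_region="zmax")
        sc = make_slab_scene(spec)
        plans = make_advance_plan(sc, "block0_1", advance_mm=(4.0, 0.0, 0.0),
                                  substeps=substeps)
        deformed, _ = run_plan(sc, plans, SolverSettings(substeps=substeps))
        return deformed.rest_positions

    x10 = run(10)
    x20 = run(20)
    assert np.linalg.norm(x10 - x20, axis=1).max() < 0.1


def test_solver_settings_validation():
    with pytest.raises(ValueError):
        SolverSettings(substeps=0)
    with pytest.raises(ValueError):
        SolverSettings(line_search_shrink=1.0)
    with pytest.raises(ValueError):
        SolverSettings(armijo_c=0.7)


def _reset(sc):
    """Return the shared scene's fragments to the rest pose."""
    for frag in sc.fragments.values():
        frag.set_pose(Transform.identity())
    sc.coupling.update_offsets(sc.fragments)
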