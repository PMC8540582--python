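"""Mesh I/O, signed distances, and geometric invariants."""

import numpy as np
import pytest

from orthosim.geometry import (
    MeshFormatError,
    MeshValidationError,
    SurfaceMesh,
    TetMesh,
    Transform,
    closest_point_query,
    read_surface,
    read_tet_mesh,
    read_vtk,
    signed_distance_query,
    weld_vertices,
    winding_number,
    write_surface,
    write_tet_mesh,
    write_vtk,
)

from conftest import box_surface, icosphere, random_tet_mesh


# --------------------------------------------------------------------------
# SurfaceMesh validation
# --------------------------------------------------------------------------


def test_surface_rejects_out_of_range_and_degenerate_faces():
    with pytest.raises(MeshValidationError, match="out of range"):
        SurfaceMesh(np.zeros((3, 3)), [[0, 1, 3]])
    with pytest.raises(MeshValidationError, match="degenerate"):
        SurfaceMesh(np.eye(3), [[0, 1, 1]])


def test_box_is_closed_open_patch_is_not():
    box = box_surface([0, 0, 0], [1, 1, 1])
    assert box.is_closed()
    patch = SurfaceMesh(box.vertices, box.faces[:6])
    assert not patch.is_closed()


# --------------------------------------------------------------------------
# OBJ / STL I/O
# --------------------------------------------------------------------------


def test_obj_single_triangle_roundtrip(tmp_path):
    p = tmp_path / "tri.obj"
    p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
    mesh = read_surface(str(p))
    assert mesh.n_vertices == 3 and mesh.n_faces == 1
    np.testing.assert_array_equal(mesh.faces, [[0, 1, 2]])


def test_obj_zero_index_is_rejected(tmp_path):
    p = tmp_path / "bad.obj"
    p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 0 1 2\n")
    with pytest.raises(MeshValidationError):
        read_surface(str(p))


def test_obj_groups_roundtrip(tmp_path):
    box = box_surface([0, 0, 0], [1, 1, 1])
    labels = np.array([0] * 6 + [1] * 6)
    tagged = SurfaceMesh(box.vertices, box.faces, labels, None, {0: "left", 1: "right"})
    p = tmp_path / "grouped.obj"
    write_surface(tagged, str(p))
    back = read_surface(str(p))
    assert back.face_group_labels is not None
    assert sorted(back.group_names.values()) == ["left", "right"]
    # same faces per group, up to face order
    for name in ("left", "right"):
        want_label = {v: k for k, v in tagged.group_names.items()}[name]
        got_label = {v: k for k, v in back.group_names.items()}[name]
        want = {tuple(f) for f in tagged.faces[labels == want_label]}
        got = {tuple(f) for f in back.faces[back.face_group_labels == got_label]}
        assert want == got


def test_stl_binary_cube_welds_to_12_faces(tmp_path):
    box = box_surface([0, 0, 0], [1, 1, 1])
    p = tmp_path / "cube.stl"
    write_surface(box, str(p))
    back = read_surface(str(p))
    assert back.n_faces == 12
    assert back.n_vertices == 8  # STL triplicates vertices; weld restores 8
    assert back.is_closed()


def test_obj_write_read_preserves_coordinates(tmp_path):
    mesh = icosphere(radius=3.0, subdivisions=1)
    p = tmp_path / "s.obj"
    write_surface(mesh, str(p))
    back = read_surface(str(p))
    np.testing.assert_allclose(back.vertices, mesh.vertices, rtol=1e-12, atol=0)
    np.testing.assert_array_equal(back.faces, mesh.faces)


def test_weld_drops_degenerate_faces():
    v = np.array([[0, 0, 0], [1e-9, 0, 0], [1, 0, 0], [0, 1, 0]], float)
    m = SurfaceMesh(v, [[0, 1, 2], [0, 2, 3]])
    w = weld_vertices(m, 1e-6)  # 0 and 1 merge; the first face collapses
    assert w.n_vertices == 3 and w.n_faces == 1


# --------------------------------------------------------------------------
# TetGen .node/.ele
# --------------------------------------------------------------------------


def _write_node_ele(tmp_path, coords, tets, base=1):
    node = tmp_path / "m.node"
    ele = tmp_path / "m.ele"
    lines = [f"{len(coords)} 3 0 0"]
    for i, c in enumerate(coords):
        lines.append(f"{i + base} {c[0]} {c[1]} {c[2]}")
    node.write_text("\n".join(lines) + "\n")
    lines = [f"{len(tets)} 4 0"]
    for i, t in enumerate(tets):
        lines.append(f"{i + base} " + " ".join(str(j + base) for j in t))
    ele.write_text("\n".join(lines) + "\n")
    return str(node), str(ele)


def test_unit_reference_tet_volume(tmp_path):
    coords = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
    mesh = read_tet_mesh(*_write_node_ele(tmp_path, coords, [[0, 1, 2, 3]]))
    np.testing.assert_allclose(mesh.quadrature_weights, [1.0 / 6.0], rtol=1e-12)


def test_two_hex_slab_reads_10_tets_volume_2(tmp_path):
    from orthosim.fixtures import _TETS_EVEN, _TETS_ODD

    # 2x1x1 mm slab: two unit hexes sharing the x=1 face
    coords = []
    for ix in range(3):
        for iy in range(2):
            for iz in range(2):
                coords.append([ix, iy, iz])

    def nid(ix, iy, iz):
        return (ix * 2 + iy) * 2 + iz

    tets = []
    for ix, pattern in ((0, _TETS_EVEN), (1, _TETS_ODD)):
        corners = np.array(
            [nid(ix + (c & 1), (c >> 1) & 1, (c >> 2) & 1) for c in range(8)]
        )
        tets.extend(corners[pattern].tolist())
    mesh = read_tet_mesh(*_write_node_ele(tmp_path, coords, tets))
    assert mesh.n_elements == 10
    np.testing.assert_allclose(mesh.total_volume(), 2.0, rtol=1e-12)
    assert mesh.boundary_surface.is_closed()


def test_index_base_equivalence(tmp_path):
    coords = [[0, 0, 0], [2, 0, 0], [0, 3, 0], [0, 0, 4]]
    m1 = read_tet_mesh(*_write_node_ele(tmp_path, coords, [[0, 1, 2, 3]], base=1))
    (tmp_path / "z").mkdir()
    m0 = read_tet_mesh(*_write_node_ele(tmp_path / "z", coords, [[0, 1, 2, 3]], base=0))
    np.testing.assert_array_equal(m0.tets, m1.tets)
    np.testing.assert_array_equal(m0.rest_positions, m1.rest_positions)


def test_zero_volume_tet_rejected(tmp_path):
    coords = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 0]]
    with pytest.raises(MeshValidationError, match="zero-volume"):
        read_tet_mesh(*_write_node_ele(tmp_path, coords, [[0, 1, 2, 3]]))


def test_tet_mesh_roundtrip_and_inverted_reorientation(tmp_path):
    mesh = random_tet_mesh(seed=5)
    write_tet_mesh(mesh, str(tmp_path / "a.node"), str(tmp_path / "a.ele"))
    back = read_tet_mesh(str(tmp_path / "a.node"), str(tmp_path / "a.ele"))
    np.testing.assert_allclose(back.rest_positions, mesh.rest_positions, rtol=1e-12)
    np.testing.assert_array_equal(back.tets, mesh.tets)
    # an inverted tet is repaired by swapping two indices
    inv = TetMesh(mesh.rest_positions, mesh.tets[:, [0, 1, 3, 2]])
    assert np.all(inv._signed_volumes() > 0)


def test_total_volume_invariant_under_rigid_motion():
    mesh = random_tet_mesh(seed=7)
    T = Transform.from_axis_angle([0.3, -0.2, 0.9], [5.0, -2.0, 1.0])
    moved = TetMesh(T.apply(mesh.rest_positions), mesh.tets.copy())
    np.testing.assert_allclose(moved.total_volume(), mesh.total_volume(), rtol=1e-9)


# --------------------------------------------------------------------------
# VTK round trip
# --------------------------------------------------------------------------


def test_vtk_roundtrip_tet_mesh_with_scalars(tmp_path):
    mesh = random_tet_mesh(seed=1)
    scal = {"signed_error_mm": np.linspace(-4, 4, mesh.n_nodes)}
    p = str(tmp_path / "m.vtk")
    write_vtk(mesh, scal, p)
    back, scalars = read_vtk(p)
    np.testing.assert_allclose(back.rest_positions, mesh.rest_positions, rtol=1e-12)
    np.testing.assert_array_equal(back.tets, mesh.tets)
    np.testing.assert_allclose(scalars["signed_error_mm"], scal["signed_error_mm"],
                               rtol=1e-12)


def test_vtk_geometry_only_and_length_mismatch(tmp_path):
    box = box_surface([0, 0, 0], [1, 2, 3])
    p = str(tmp_path / "b.vtk")
    write_vtk(box, {}, p)
    back, scalars = read_vtk(p)
    assert scalars == {} and back.n_faces == 12
    with pytest.raises(MeshValidationError, match="scalar"):
        write_vtk(box, {"bad": np.zeros(3)}, p)


# --------------------------------------------------------------------------
# Signed distance
# --------------------------------------------------------------------------


def test_signed_distance_sphere_center_is_minus_radius():
    sph = icosphere(radius=10.0)
    d = signed_distance_query([[0.0, 0.0, 0.0]], sph)[0]
    assert d < 0
    assert abs(d + 10.0) < 0.5  # faceting of the subdivision-2 icosphere


def test_signed_distance_on_vertex_is_zero_and_outside_cube_positive():
    cube = box_surface([0, 0, 0], [1, 1, 1])
    d = signed_distance_query([cube.vertices[0], [0.5, 0.5, 6.0]], cube)
    assert abs(d[0]) < 1e-12
    np.testing.assert_allclose(d[1], 5.0, atol=1e-12)


def test_open_surface_needs_flag():
    cube = box_surface([0, 0, 0], [1, 1, 1])
    patch = SurfaceMesh(cube.vertices, cube.faces[:6])
    with pytest.raises(MeshValidationError):
        signed_distance_query([[0.5, 0.5, 2.0]], patch)
    d = signed_distance_query([[0.5, 0.5, 2.0]], patch, allow_open=True)
    assert np.isfinite(d[0])


def _closest_on_triangle_oracle(p, a, b, c):
    """Independent closest point: plane projection if inside, else best of
    the three clamped edge projections."""
    n = np.cross(b - a, c - a)
    n2 = n @ n
    candidates = []
    if n2 > 0:
        q = p - ((p - a) @ n) / n2 * n
        # barycentric inside test
        T = np.column_stack([b - a, c - a])
        st, *_ = np.linalg.lstsq(T, q - a, rcond=None)
        if st[0] >= -1e-12 and st[1] >= -1e-12 and st.sum() <= 1 + 1e-12:
            candidates.append(q)
    for u, v in ((a, b), (b, c), (c, a)):
        t = np.clip((p - u) @ (v - u) / ((v - u) @ (v - u)), 0.0, 1.0)
        candidates.append(u + t * (v - u))
    return min(candidates, key=lambda q: np.linalg.norm(p - q))


def test_closest_point_matches_independent_oracle():
    sph = icosphere(radius=5.0, subdivisions=1, scale=(1.0, 0.7, 1.3))
    rng = np.random.default_rng(11)
    pts = rng.uniform(-8, 8, (40, 3))
    dist, closest, _ = closest_point_query(pts, sph)
    tri = sph.triangles()
    for k, p in enumerate(pts):
        best = min(
            (np.linalg.norm(p - _closest_on_triangle_oracle(p, *t)) for t in tri)
        )
        assert abs(dist[k] - best) < 1e-9


def test_winding_number_inside_outside():
    box = box_surface([0, 0, 0], [2, 2, 2])
    wn = winding_number(np.array([[1.0, 1.0, 1.0], [5.0, 1.0, 1.0]]), box)
    np.testing.assert_allclose(wn, [1.0, 0.0], atol=1e-9)


# --------------------------------------------------------------------------
# Transform
# --------------------------------------------------------------------------


def test_transform_validates_rotation():
    with pytest.raises(MeshValidationError):
        Transform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


def test_transform_compose_inverse_roundtrip():
    rng = np.random.default_rng(3)
    for _ in range(10):
        T = Transform.from_axis_angle(rng.normal(size=3), rng.normal(size=3))
        I = T.compose(T.inverse())
        np.testing.assert_allclose(I.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(I.translation, 0.0, atol=1e-12)
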