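"""Synthetic-torso generator: determinism, grade semantics, ground truth."""

import numpy as np
import pytest
import trimesh

from ibccontour.errors import ValidationError
from ibccontour.synthetic import (
    SAG_BY_GRADE,
    TorsoParams,
    generate_analytic_surface,
    generate_torso,
)

from conftest import mirror_mesh

DOWN = np.array([0.0, -1.0, 0.0])
COS10 = np.cos(np.radians(10.0))


def _coarse(grade, seed=1, noise_mm=0.3, **kw):
    return TorsoParams(grade=grade, seed=seed, edge_length=3.0,
                       noise_mm=noise_mm, **kw)


def test_same_seed_is_bit_identical():
    a = generate_torso(_coarse(2, seed=9))
    b = generate_torso(_coarse(2, seed=9))
    assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
    assert np.array_equal(a.mesh.faces, b.mesh.faces)
    c = generate_torso(_coarse(2, seed=10))
    assert not np.array_equal(a.mesh.vertices, c.mesh.vertices)


def test_grade0_has_no_downward_faces():
    case = generate_torso(_coarse(0))
    normals = case.mesh.face_normals()
    assert not np.any(normals @ DOWN >= COS10)  # brute-force scan
    assert case.lvp["left"] is None and case.lvp["right"] is None


@pytest.mark.parametrize("grade", [1, 2, 3])
def test_ptotic_grades_have_overhang_below_the_crease(grade):
    case = generate_torso(_coarse(grade))
    normals = case.mesh.face_normals()
    assert np.any(normals @ DOWN >= COS10)
    for side in ("left", "right"):
        lvp = case.lvp[side]
        assert lvp is not None
        assert lvp[1] < case.crease[side].points[:, 1].min()


def test_lvp_height_monotone_in_grade():
    ys = []
    for grade in (1, 2, 3):
        case = generate_torso(_coarse(grade))
        ys.append(case.lvp["right"][1])
    assert ys[0] > ys[1] > ys[2]
    assert SAG_BY_GRADE[1] < SAG_BY_GRADE[2] < SAG_BY_GRADE[3]


def test_mirror_symmetry():
    # noiseless: the vertex set is bitwise invariant under x -> -x
    clean = generate_torso(_coarse(2, seed=4, noise_mm=0.0))
    as_set = lambda verts, nd: {tuple(np.round(p, nd)) for p in verts}
    assert {tuple(p) for p in clean.mesh.vertices} == {
        tuple(p) for p in mirror_mesh(clean.mesh).vertices
    }
    # with noise the displacement rides on accumulated vertex normals, whose
    # mirror symmetry holds to floating-point accumulation order (~1 ulp)
    case = generate_torso(_coarse(2, seed=4))
    assert as_set(case.mesh.vertices, 9) == as_set(
        mirror_mesh(case.mesh).vertices, 9
    )
    # ground truth mirrors exactly too
    left = case.crease["left"].points
    right = case.crease["right"].points
    assert np.allclose(left[:, 0], -right[:, 0], atol=1e-12)
    assert np.allclose(left[:, 1:], right[:, 1:], atol=1e-12)
    assert case.lvp["left"][0] == pytest.approx(-case.lvp["right"][0], abs=1e-6)


def _point_to_mesh_distance(mesh, points, prefilter=40):
    """Exact point-to-triangle distances via a centroid-KDTree prefilter."""
    from scipy.spatial import cKDTree

    tris = mesh.vertices[mesh.faces]
    centroids = tris.mean(axis=1)
    _, cand = cKDTree(centroids).query(points, k=prefilter)
    out = np.empty(len(points))
    for i, (p, faces_i) in enumerate(zip(points, cand)):
        closest = trimesh.triangles.closest_point(
            tris[faces_i], np.tile(p, (len(faces_i), 1))
        )
        out[i] = np.linalg.norm(closest - p, axis=1).min()
    return out


@pytest.mark.parametrize("edge", [3.0, 1.5])
def test_crease_lies_on_the_mesh_surface(edge):
    params = TorsoParams(grade=1, seed=2, edge_length=edge, noise_mm=0.0)
    case = generate_torso(params)
    for side in ("left", "right"):
        dist = _point_to_mesh_distance(case.mesh, case.crease[side].points)
        assert np.max(dist) <= edge / 2.0


def test_noise_rms_matches_request():
    clean = generate_torso(_coarse(0, seed=5, noise_mm=0.0))
    noisy = generate_torso(_coarse(0, seed=5, noise_mm=0.3))
    disp = np.linalg.norm(noisy.mesh.vertices - clean.mesh.vertices, axis=1)
    assert np.sqrt(np.mean(disp**2)) == pytest.approx(0.3, rel=0.05)


def test_hole_is_cut_where_requested():
    case = generate_torso(_coarse(0, hole=(72.0, 140.0, 9.0)))
    from ibccontour.mesh_io import detect_holes

    loops = detect_holes(case.mesh)
    assert len(loops) == 2
    assert np.hypot(loops[1].centroid[0] - 72, loops[1].centroid[1] - 140) < 12


def test_parameter_validation():
    with pytest.raises(ValidationError, match="edge_length"):
        TorsoParams(edge_length=20.0).validate()
    with pytest.raises(ValidationError, match="noise"):
        TorsoParams(noise_mm=2.0).validate()
    with pytest.raises(ValidationError, match="grade"):
        TorsoParams(grade=5).validate()
    with pytest.raises(ValidationError, match="hole"):
        TorsoParams(hole=(0.0, 0.0, -1.0)).validate()
    with pytest.raises(ValidationError):
        generate_analytic_surface("sphere", -1.0, 1.0)
    with pytest.raises(ValidationError, match="unknown"):
        generate_analytic_surface("torus", 50.0, 1.5)


def test_analytic_surfaces_sample_their_formulas():
    saddle = generate_analytic_surface("saddle", 100.0, 3.0)
    x, y, z = saddle.vertices.T
    assert np.allclose(z, (x**2 - y**2) / 200.0, atol=1e-9)
    sphere = generate_analytic_surface("sphere", 50.0, 1.5)
    assert sphere.n_vertices >= 2000
    assert np.allclose(np.linalg.norm(sphere.vertices, axis=1), 50.0, atol=1e-9)
    cyl = generate_analytic_surface("cylinder", 40.0, 3.0)
    r = np.hypot(cyl.vertices[:, 0], cyl.vertices[:, 2])
    assert np.allclose(r, 40.0, atol=1e-9)
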