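"""Angle/sector computation, point M, intermediate point, extension, spline."""

import numpy as np
import pytest

from ibccontour.candidates import CandidateSet
from ibccontour.contour import (
    _arc_length_limit,
    compute_angles,
    extend_contour,
    find_intermediate_point,
    find_point_M,
    fit_spline,
    verify_chain,
)
from ibccontour.curvature import CurvatureField
from ibccontour.errors import ContourError
from ibccontour.mesh_io import TriangleMesh
from ibccontour.refpoint import ReferencePoint


def _make_scene(points, kmin=None, normals=None):
    """A candidate set over an explicit point cloud (geometry stub)."""
    pts = np.asarray(points, float)
    mesh = TriangleMesh(pts, np.array([[0, 1, 2]]), "stub")
    n = len(pts)
    fld = CurvatureField(
        mesh=mesh,
        kmax=np.zeros(n),
        kmin=np.zeros(n) if kmin is None else np.asarray(kmin, float),
        normal=(np.tile([0.0, 0.0, 1.0], (n, 1)) if normals is None
                else np.asarray(normals, float)),
        is_boundary=np.zeros(n, bool),
        S=-np.ones(n),
    )
    spp = CandidateSet(indices=np.arange(n), kmean=0.0, field=fld)
    return mesh, fld, spp


RP = ReferencePoint(x=0.0, y=100.0, side="right",
                    block_a_center=(0.0, 95.0), block_b_center=(0.0, 100.0))


def test_angles_cardinal_directions():
    pts = [
        [0.0, 0.0, 0.0],     # directly below RP -> 0 deg
        [50.0, 100.0, 0.0],  # same y, +x -> +90
        [-50.0, 100.0, 0.0],  # same y, -x -> -90
        [1e-9, 200.0, 0.0],   # just above, +x perturbation -> ~ +180
        [-1e-9, 200.0, 0.0],  # just above, -x perturbation -> ~ -180
    ]
    _, _, spp = _make_scene(pts)
    part = compute_angles(spp, RP)
    theta = {v: t for v, t in zip(part.vertex_indices, part.theta)}
    assert theta[0] == pytest.approx(0.0, abs=1e-9)
    assert theta[1] == pytest.approx(90.0)
    assert theta[2] == pytest.approx(-90.0)
    assert theta[3] == pytest.approx(180.0, abs=1e-6)
    assert theta[4] == pytest.approx(-180.0, abs=1e-6)
    assert np.all(np.diff(part.theta) >= 0)  # sorted by angle


def test_angles_coincident_candidate_warns():
    _, _, spp = _make_scene([[0.0, 100.0, 5.0], [10.0, 0.0, 0.0], [0, 0, 0]])
    part = compute_angles(spp, RP)
    theta = {v: t for v, t in zip(part.vertex_indices, part.theta)}
    assert theta[0] == 0.0  # coincides with RP in (x, y)


def test_sector_boundaries():
    # sector k covers [5k - 2.5, 5k + 2.5)
    y = 100.0 - 100.0 * np.cos(np.radians([2.4, 2.6]))
    x = 100.0 * np.sin(np.radians([2.4, 2.6]))
    _, _, spp = _make_scene([[x[0], y[0], 0], [x[1], y[1], 0], [0, 0, 0]])
    part = compute_angles(spp, RP)
    sector = {v: s for v, s in zip(part.vertex_indices, part.sector)}
    assert sector[0] == 0 and sector[1] == 1


def test_point_m_flat_plane_tie_break():
    # equal normals everywhere -> all NOA = 0 -> smallest vertex index wins
    pts = [[dx, 0.0, 0.0] for dx in (-2.0, -1.0, 0.0, 1.0, 2.0)]
    _, fld, spp = _make_scene(pts)
    part = compute_angles(spp, RP)
    assert find_point_M(part, fld) == 0


def test_point_m_contract_errors():
    # singleton sector 0 -> abort
    _, fld, spp = _make_scene([[0.0, 0.0, 0.0], [80.0, 100.0, 0.0], [0, 5, 0]])
    part = compute_angles(
        CandidateSet(indices=np.array([0, 1]), kmean=0.0, field=fld), RP
    )
    with pytest.raises(ContourError, match="intermediate sector"):
        find_point_M(part, fld)
    # two candidates 15 mm apart with radius 10 -> all NOA undefined -> abort
    _, fld2, spp2 = _make_scene([[0, 0, 0], [0, 15, 0], [50, 100, 0]])
    part2 = compute_angles(spp2, RP)
    with pytest.raises(ContourError, match="within 10"):
        find_point_M(part2, fld2, radius=10.0)


def test_point_m_prefers_sharpest_normal_change():
    normals = [[0, 0, 1], [0, 0, 1], [np.sin(1.0), 0, np.cos(1.0)], [0, 0, 1]]
    pts = [[-12, 0, 0], [1, 0, 0], [2, 1, 0], [9, 0, 0]]
    _, fld, spp = _make_scene(pts, normals=normals)
    part = compute_angles(spp, RP)
    # vertices 1-3 see the tilted normal within 10 mm: their NOA is 1 rad;
    # vertex 0 is out of range of it; ties break to the lowest vertex index
    assert find_point_M(part, fld) == 1


def test_intermediate_point_minimum_kmin_ball():
    pts = [[0, 0, 0], [4, 0, 0], [9, 0, 0], [30, 0, 0]]
    kmin = [-0.1, -0.05, -0.5, -9.0]
    _, fld, spp = _make_scene(pts, kmin=kmin)
    # vertex 3 has the lowest kmin overall but is outside the 10 mm ball
    assert find_intermediate_point(0, spp, fld, radius=10.0) == 2
    # brute-force oracle over the ball
    d = np.linalg.norm(np.asarray(pts) - pts[0], axis=1)
    ball = np.nonzero(d <= 10.0)[0]
    assert ball[np.argmin(np.asarray(kmin)[ball])] == 2
    # M alone in the ball -> M itself
    _, fld1, spp1 = _make_scene([[0, 0, 0], [50, 0, 0], [99, 0, 0]],
                                kmin=[-0.1, -0.2, -0.3])
    assert find_intermediate_point(0, spp1, fld1, radius=10.0) == 0


def test_arc_length_limit_hand_value():
    # R = 114.59 mm  =>  L = (5 deg in rad) * R = 10.0 mm, acceptance 2L = 20
    prev = np.array([0.0, 100.0 - 114.59, 0.0])
    assert _arc_length_limit(RP, prev, 5.0) == pytest.approx(20.0, abs=0.01)


def test_extension_respects_2l_and_min_kmin():
    # sector 1 offers: far candidate with lowest kmin (violates 2L) and a
    # near milder one -> the near one must be chosen
    theta1 = np.radians(5.0)
    r_near, r_far = 102.0, 126.0  # steps ~8.9 mm and ~26 mm from the start
    pts = [
        [0.0, 0.0, 0.0],  # intermediate (sector 0), R = 100 -> 2L = 17.45
        [r_near * np.sin(theta1), 100 - r_near * np.cos(theta1), 0.0],
        [r_far * np.sin(theta1), 100 - r_far * np.cos(theta1), 0.0],
    ]
    kmin = [-1.0, -0.1, -0.9]
    _, fld, spp = _make_scene(pts, kmin=kmin)
    part = compute_angles(spp, RP)
    res = extend_contour(0, part, fld, RP)
    assert list(res.vertex_indices) == [0, 1]
    assert res.termination["increasing"] == "no-candidate"
    assert res.termination["decreasing"] == "no-candidate"
    assert verify_chain(res)


def test_extension_terminates_on_2l():
    theta1 = np.radians(5.0)
    pts = [
        [0.0, 0.0, 0.0],
        [130 * np.sin(theta1), 100 - 130 * np.cos(theta1), 0.0],  # 30 mm away
    ]
    _, fld, spp = _make_scene(pts + [[0, 190, 0]], kmin=[-1, -1, -1])
    part = compute_angles(spp, RP)
    res = extend_contour(0, part, fld, RP)
    assert res.termination["increasing"] == "distance>2L"
    assert len(res) == 1


def test_verify_chain_detects_corruption(default_detection):
    sr = default_detection.sides["right"]
    assert verify_chain(sr.contour)
    broken = sr.contour
    pts = broken.points.copy()
    pts[-1] = pts[-1] + [80.0, 0.0, 0.0]
    import dataclasses

    bad = dataclasses.replace(broken, points=pts)
    assert not verify_chain(bad)


def test_spline_collinear_and_interpolation():
    line = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]], float)
    sc = fit_spline(line, n_samples=50)
    assert np.all(np.abs(sc.samples[:, 1:]) < 1e-9)
    pts = np.array([[0, 0, 0], [10, 5, 1], [18, 12, 0], [30, 14, -2]], float)
    sc = fit_spline(pts, n_samples=200)
    for p, t in zip(pts, sc.parameter):
        assert np.allclose(sc.spline(t), p, atol=1e-12)
    with pytest.raises(ContourError, match="too short"):
        fit_spline(pts[:3])


def test_spline_tracks_a_circle():
    ang = np.radians(np.arange(0, 181, 5))
    circle = np.column_stack(
        [100 * np.cos(ang), 100 * np.sin(ang), np.zeros(len(ang))]
    )
    sc = fit_spline(circle, n_samples=500)
    radii = np.linalg.norm(sc.samples[:, :2], axis=1)
    assert np.max(np.abs(radii - 100.0)) < 0.1


def test_detection_is_deterministic(default_case):
    from ibccontour.pipeline import detect

    r1 = detect(default_case.mesh)
    r2 = detect(default_case.mesh)
    for side in ("left", "right"):
        assert np.array_equal(
            r1.sides[side].contour.vertex_indices,
            r2.sides[side].contour.vertex_indices,
        )
        assert np.array_equal(
            r1.sides[side].spline.samples, r2.sides[side].spline.samples
        )
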