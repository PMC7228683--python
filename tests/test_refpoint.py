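"""Side split, weighted shape-index block grid, reference-point location."""

import numpy as np
import pytest

from ibccontour.curvature import CurvatureField, principal_curvatures, shape_index
from ibccontour.errors import SideError
from ibccontour.mesh_io import TriangleMesh
from ibccontour.refpoint import (
    BlockGrid,
    build_block_grid,
    locate_reference_point,
    split_sides,
)
from ibccontour.synthetic import TorsoParams, generate_torso

from conftest import mirror_mesh


def test_split_sides_symmetric(coarse_case):
    sides = split_sides(coarse_case.mesh)
    nl, nr = len(sides["left"]), len(sides["right"])
    assert abs(nl - nr) / max(nl, nr) < 0.05


def test_split_sides_mirror_swap(coarse_case):
    mesh = coarse_case.mesh
    sides = split_sides(mesh)
    flipped = split_sides(mirror_mesh(mesh))
    # vertex order is preserved by mirroring, so index sets swap exactly,
    # except exact-midline vertices which go to the right side in both
    mid = (mesh.vertices[:, 0].min() + mesh.vertices[:, 0].max()) / 2.0
    off_mid = set(np.nonzero(mesh.vertices[:, 0] != mid)[0])
    assert set(flipped["left"]) & off_mid == set(sides["right"]) & off_mid
    assert set(flipped["right"]) & off_mid == set(sides["left"]) & off_mid


def test_split_sides_sparse_error():
    rng = np.random.default_rng(0)
    xy = rng.uniform(0, 50, size=(300, 2))
    verts = np.column_stack([xy[:, 0], xy[:, 1], np.zeros(300)])
    verts[0, 0] = 500.0  # lone right-side vertex
    faces = np.array([[i, i + 1, i + 2] for i in range(1, 297)])
    mesh = TriangleMesh(verts, faces, "sparse")
    with pytest.raises(SideError, match="too sparse"):
        split_sides(mesh)


def _stub_field(mesh, S):
    return CurvatureField(
        mesh=mesh,
        kmax=np.zeros(mesh.n_vertices),
        kmin=np.zeros(mesh.n_vertices),
        normal=np.zeros((mesh.n_vertices, 3)),
        is_boundary=np.zeros(mesh.n_vertices, bool),
        S=np.asarray(S, float),
    )


def _tiny_mesh(points):
    pts = np.asarray(points, float)
    faces = np.array([[0, 1, 2]])  # geometry irrelevant for the grid math
    return TriangleMesh(pts, faces, "stub")


def test_block_average_formula_by_hand():
    # a block holding one vertex with S=0.5, z = z_min + 10 => ave_S = 5.0
    mesh = _tiny_mesh([[1.0, 1.0, 10.0], [7.0, 2.0, 0.0], [8.0, 1.0, 0.0]])
    fld = _stub_field(mesh, [0.5, 0.0, 0.0])
    grid = build_block_grid(mesh, np.array([0, 1, 2]), fld, "right",
                            block_size=5.0, x_anchor=0.0)
    assert grid.z_min == 0.0
    block0 = np.nonzero((grid.cols == 0) & (grid.rows == 0))[0][0]
    assert grid.ave_s[block0] == pytest.approx(0.5 * 10 / 1)

    # all-zero shape index => every block average is zero
    fld0 = _stub_field(mesh, [0.0, 0.0, 0.0])
    grid0 = build_block_grid(mesh, np.array([0, 1, 2]), fld0, "right",
                             block_size=5.0, x_anchor=0.0)
    assert np.all(grid0.ave_s == 0.0)

    # a vertex exactly at z_min contributes nothing regardless of its S
    fldz = _stub_field(mesh, [0.0, 1.0, 0.0])  # S=1 at the z_min vertex
    gridz = build_block_grid(mesh, np.array([0, 1, 2]), fldz, "right",
                             block_size=5.0, x_anchor=0.0)
    assert np.all(gridz.ave_s == 0.0)


def _grid(cols, rows, ave_s, side="right"):
    return BlockGrid(
        side=side, block_size=5.0, x_anchor=0.0, y_anchor=0.0, z_min=0.0,
        cols=np.asarray(cols), rows=np.asarray(rows),
        ave_s=np.asarray(ave_s, float), counts=np.ones(len(cols), int),
    )


def test_reference_point_single_block_and_fallback():
    grid = _grid([2], [3], [1.0])
    rp = locate_reference_point(grid)
    assert rp.fallback_b_is_a  # nothing above block A
    assert (rp.x, rp.y) == (12.5, 17.5)  # A's own centre


def test_reference_point_window_and_b_selection():
    # A at (col 4, row 2); candidate Bs above within +-3 columns, 10 rows
    cols = [4, 4, 7, 4, 8]
    rows = [2, 8, 9, 13, 5]
    ave = [9.0, 0.5, 0.4, 0.8, 0.7]
    rp = locate_reference_point(_grid(cols, rows, ave))
    # row 13 is outside the 10-row window and col 8 outside +-3 columns;
    # of the remaining positive blocks the highest is (col 7, row 9) => B
    assert rp.x == pytest.approx(4 * 5 + 2.5)  # x always from block A
    assert rp.y == pytest.approx(9 * 5 + 2.5)
    assert rp.block_b_center[0] == pytest.approx(7 * 5 + 2.5)
    assert rp.y >= rp.block_a_center[1]


def test_reference_point_tie_break_row_major():
    # two equal maxima: bottom row first, then lowest column index
    rp = locate_reference_point(_grid([3, 1], [5, 2], [7.0, 7.0]))
    assert rp.block_a_center == (1 * 5 + 2.5, 2 * 5 + 2.5)


def test_rp_mirror_equivariance(coarse_case):
    mesh = coarse_case.mesh
    fld = shape_index(principal_curvatures(mesh))
    sides = split_sides(mesh)
    rp_r = locate_reference_point(
        build_block_grid(mesh, sides["right"], fld, "right")
    )
    m2 = mirror_mesh(mesh)
    fld2 = shape_index(principal_curvatures(m2))
    sides2 = split_sides(m2)
    rp_l2 = locate_reference_point(
        build_block_grid(m2, sides2["left"], fld2, "left")
    )
    assert rp_l2.x == pytest.approx(-rp_r.x, abs=1e-9)
    assert rp_l2.y == pytest.approx(rp_r.y, abs=1e-9)


@pytest.mark.parametrize("grade", [0, 1, 2, 3])
def test_rp_lands_on_the_mound(grade):
    """RP must sit on the breast mound: laterally within 10 mm of the apex
    column and vertically within the (possibly sagged) mound span."""
    for seed in (1, 2):
        # 2 mm spacing: the upper end of the point density the block
        # statistics are designed for (~9 points per 5 mm block)
        params = TorsoParams(grade=grade, seed=seed, edge_length=2.0,
                             noise_mm=0.3)
        case = generate_torso(params)
        mesh = case.mesh
        fld = shape_index(principal_curvatures(mesh))
        sides = split_sides(mesh)
        for side, cx in (("left", -params.breast_offset_x),
                         ("right", params.breast_offset_x)):
            rp = locate_reference_point(
                build_block_grid(mesh, sides[side], fld, side)
            )
            # the z-weighted average is biased a little toward the sternum
            # (the chest wall rises medially), so allow up to 4 block widths
            assert abs(rp.x - cx) <= 20.0, f"grade {grade} {side}: RP lateral"
            y_lo = params.breast_center_y - params.breast_radius
            y_hi = params.breast_center_y + params.breast_radius + 5.0
            assert y_lo <= rp.y <= y_hi, f"grade {grade} {side}: RP height"
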