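"""Per-breast reference point from a weighted-shape-index block grid.

The torso is split at the ROI midline into left and right halves.  Each
half's vertices are tiled into 5 mm x 5 mm blocks in the x-y plane, and each
block i gets the z-weighted shape-index average

    ave_S_i = sum_j S_ij * z_ij / n_i ,    z_ij = z_orig_ij - z_min ,

where z_min is the minimum z over the half, so every weight is non-negative.
The weighting favours convex (S > 0) regions that protrude forward -- the
breast mound.  Block A is the block with the largest ave_S; a search window
of 7 x 10 blocks above A (A's column +- 3 columns = +-15 mm laterally, 50 mm
up) is scanned and the highest block with ave_S > 0 becomes block B.  The
reference point RP combines A's column with B's row: (x_A_center,
y_B_center).  RP sits on the mound above where the lower pole turns toward
the chest wall; no nipple is required.

Block x-edges are anchored at the ROI midline (for the right half this is
its minimal-x corner) and y-edges at each side's minimum y.  Midline
anchoring makes the construction exactly equivariant under mirroring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .curvature import CurvatureField
from .errors import SideError
from .mesh_io import TriangleMesh

log = logging.getLogger(__name__)

__all__ = ["BlockGrid", "ReferencePoint", "split_sides", "build_block_grid",
           "locate_reference_point"]

MIN_SIDE_VERTICES = 100
DEFAULT_BLOCK_MM = 5.0
WINDOW_COLS_EACH_SIDE = 3  # +-15 mm at 5 mm blocks
WINDOW_ROWS_UP = 10  # 50 mm at 5 mm blocks


@dataclass
class BlockGrid:
    """Per-block weighted shape index over one torso half."""

    side: str  # "left" or "right"
    block_size: float  # mm
    x_anchor: float  # block x-edges at x_anchor + k * block_size
    y_anchor: float
    z_min: float  # z normalisation offset for this side
    cols: np.ndarray  # (nb,) int column of each non-empty block
    rows: np.ndarray  # (nb,) int row
    ave_s: np.ndarray  # (nb,) weighted shape-index average
    counts: np.ndarray  # (nb,) vertices per block

    def center(self, col: int, row: int) -> tuple[float, float]:
        bs = self.block_size
        return (self.x_anchor + (col + 0.5) * bs, self.y_anchor + (row + 0.5) * bs)


@dataclass
class ReferencePoint:
    """Angular origin for contour tracing on one breast (x, y only)."""

    x: float
    y: float
    side: str
    block_a_center: tuple[float, float]
    block_b_center: tuple[float, float]
    fallback_b_is_a: bool = False

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


def split_sides(mesh: TriangleMesh) -> dict[str, np.ndarray]:
    """Partition vertex indices at the midline x; midline ties go right."""
    x = mesh.vertices[:, 0]
    mid = (x.min() + x.max()) / 2.0
    right = np.nonzero(x >= mid)[0]
    left = np.nonzero(x < mid)[0]
    for name, idx in (("left", left), ("right", right)):
        if len(idx) < MIN_SIDE_VERTICES:
            raise SideError(
                f"{name} side too sparse: {len(idx)} vertices "
                f"(need >= {MIN_SIDE_VERTICES})"
            )
    return {"left": left, "right": right, "midline": mid}


def build_block_grid(
    mesh: TriangleMesh,
    side_vertices: np.ndarray,
    field: CurvatureField,
    side: str,
    block_size: float = DEFAULT_BLOCK_MM,
    x_anchor: float | None = None,
) -> BlockGrid:
    """Tile one half into blocks and compute ave_S per block."""
    if field.S is None:
        raise SideError("shape index not populated")
    pts = mesh.vertices[side_vertices]
    if x_anchor is None:
        x = mesh.vertices[:, 0]
        mid = (x.min() + x.max()) / 2.0
        # anchor at the midline; for the left side blocks grow toward -x so
        # mirroring maps block edges onto block edges exactly
        x_anchor = mid
    y_anchor = pts[:, 1].min()
    z_min = pts[:, 2].min()

    if side == "right":
        cols = np.floor((pts[:, 0] - x_anchor) / block_size).astype(int)
    else:
        # mirror image of the right-side binning: column 0 is adjacent to the
        # midline, increasing toward -x
        cols = np.floor((x_anchor - pts[:, 0]) / block_size).astype(int)
    rows = np.floor((pts[:, 1] - y_anchor) / block_size).astype(int)

    weight = field.S[side_vertices] * (pts[:, 2] - z_min)
    key = cols.astype(np.int64) * (rows.max() + 1) + rows
    uniq, inv = np.unique(key, return_inverse=True)
    sums = np.bincount(inv, weights=weight)
    counts = np.bincount(inv)
    ucols = (uniq // (rows.max() + 1)).astype(int)
    urows = (uniq % (rows.max() + 1)).astype(int)
    return BlockGrid(
        side=side,
        block_size=block_size,
        x_anchor=x_anchor,
        y_anchor=y_anchor,
        z_min=z_min,
        cols=ucols,
        rows=urows,
        ave_s=sums / counts,
        counts=counts,
    )


def _grid_center_xy(grid: BlockGrid, col: int, row: int) -> tuple[float, float]:
    bs = grid.block_size
    if grid.side == "right":
        xc = grid.x_anchor + (col + 0.5) * bs
    else:
        xc = grid.x_anchor - (col + 0.5) * bs
    return (xc, grid.y_anchor + (row + 0.5) * bs)


def locate_reference_point(grid: BlockGrid) -> ReferencePoint:
    """Pick block A (max ave_S), block B (highest ave_S>0 in the window), RP.

    Ties are broken row-major, bottom row first, then lowest column index
    (for the left side, columns count outward from the midline).
    """
    if len(grid.ave_s) == 0:
        raise SideError(f"{grid.side}: empty block grid")
    # tie-break: order blocks by (row, col) and take the first argmax
    order = np.lexsort((grid.cols, grid.rows))
    ave = grid.ave_s[order]
    a_pos = order[int(np.argmax(ave))]
    a_col, a_row = int(grid.cols[a_pos]), int(grid.rows[a_pos])

    in_window = (
        (np.abs(grid.cols - a_col) <= WINDOW_COLS_EACH_SIDE)
        & (grid.rows > a_row)
        & (grid.rows <= a_row + WINDOW_ROWS_UP)
        & (grid.ave_s > 0)
    )
    fallback = not np.any(in_window)
    if fallback:
        b_col, b_row = a_col, a_row
        log.warning(
            "%s: no positive ave_S block above A; falling back to B = A",
            grid.side,
        )
    else:
        wrows = grid.rows[in_window]
        wcols = grid.cols[in_window]
        top = wrows.max()
        at_top = wrows == top
        b_row = int(top)
        b_col = int(wcols[at_top].min())

    ax, ay = _grid_center_xy(grid, a_col, a_row)
    bx, by = _grid_center_xy(grid, b_col, b_row)
    return ReferencePoint(
        x=ax,
        y=by,
        side=grid.side,
        block_a_center=(ax, ay),
        block_b_center=(bx, by),
        fallback_b_is_a=fallback,
    )
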