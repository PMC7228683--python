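"""Lowest visible point from downward-facing triangles under the overhang.

Faces whose outward normal lies within a cone (default 10 degrees) of the
downward direction (-y) are collected; their vertices are filtered to those
lying laterally between the detected contour's two endpoint knots; the
lowest-y survivor is the LVP.  When no face points downward the breast has no
overhang (ptosis grade 0) and the LVP is reported absent: the lowest visible
contour then coincides with the inframammary fold itself.

The cone axis is configurable (+z available for sensitivity checks), but the
gravity axis of the coordinate convention is -y and is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contour import ContourResult
from .errors import ContourError
from .mesh_io import TriangleMesh

log = logging.getLogger(__name__)

__all__ = ["LowestVisiblePoint", "face_normal", "detect_lvp"]

DEFAULT_CONE_DEG = 10.0
AXES = {"-y": np.array([0.0, -1.0, 0.0]), "+z": np.array([0.0, 0.0, 1.0])}


@dataclass
class LowestVisiblePoint:
    """Result of the LVP search on one breast."""

    present: bool
    position: np.ndarray | None  # (3,) mm
    vertex_index: int  # -1 when absent
    n_candidates: int  # vertices that passed cone + lateral filters
    side: str = ""


def face_normal(v0, v1, v2) -> np.ndarray:
    """Unit normal a x b of a triangle with side vectors a, b (winding order)."""
    a = np.asarray(v1, dtype=float) - np.asarray(v0, dtype=float)
    b = np.asarray(v2, dtype=float) - np.asarray(v0, dtype=float)
    n = np.cross(a, b)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ContourError(f"zero-area face at vertices {v0}, {v1}, {v2}")
    return n / norm


def detect_lvp(
    mesh: TriangleMesh,
    contour: ContourResult,
    cone_deg: float = DEFAULT_CONE_DEG,
    axis: str = "-y",
) -> LowestVisiblePoint:
    """Find the lowest downward-facing point between the contour endpoints."""
    down = AXES[axis]
    normals = mesh.face_normals()
    cos_cone = np.cos(np.radians(cone_deg))
    in_cone = normals @ down >= cos_cone
    if not np.any(in_cone):
        log.info("%s: no downward-facing faces; LVP absent (no overhang)",
                 contour.rp.side if contour.rp else "?")
        return LowestVisiblePoint(
            present=False,
            position=None,
            vertex_index=-1,
            n_candidates=0,
            side=contour.rp.side if contour.rp else "",
        )
    cand = np.unique(mesh.faces[in_cone].ravel())
    x0, x1 = contour.points[0, 0], contour.points[-1, 0]
    lo, hi = min(x0, x1), max(x0, x1)
    xs = mesh.vertices[cand, 0]
    cand = cand[(xs > lo) & (xs < hi)]
    if len(cand) == 0:
        return LowestVisiblePoint(
            present=False,
            position=None,
            vertex_index=-1,
            n_candidates=0,
            side=contour.rp.side if contour.rp else "",
        )
    ys = mesh.vertices[cand, 1]
    best = ys.min()
    vid = int(cand[ys == best].min())  # lowest y; ties to smallest vertex id
    return LowestVisiblePoint(
        present=True,
        position=mesh.vertices[vid].copy(),
        vertex_index=vid,
        n_candidates=int(len(cand)),
        side=contour.rp.side if contour.rp else "",
    )
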