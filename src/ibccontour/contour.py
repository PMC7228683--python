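"""Contour tracing: sector partition, intermediate point, curvature extension.

Every candidate point gets an angle about the reference point RP,

    theta = sign(x_p - x_RP) * acos( v1 . v2 / (|v1| |v2|) ) ,

with v1 along -y and v2 = (x_p - x_RP, y_p - y_RP); theta = 0 points straight
down, positive angles toward +x.  Candidates are partitioned into 5-degree
sectors (sector k covers [5k - 2.5, 5k + 2.5) degrees).

Tracing starts in the sector below RP.  There the candidate M with the
sharpest local shape change is found: for each candidate, the normal angle
NOA is the maximum angle between its one-ring vertex normal and that of any
other candidate within 10 mm; M maximises NOA.  The intermediate point -- the
first accepted contour point -- is the candidate within 10 mm of M with the
minimum kmin (the deepest crease point near M).

From the intermediate point the contour is extended sector by sector in both
angular directions.  In each new sector the candidate with minimal kmin is
accepted among those closer than 2L to the previously accepted point, where

    L = (5 pi / 180) * R

is the sector arc length at radius R, and R is the (x, y)-plane distance from
RP to the previous point.  2L is the largest plausible gap between contour
points of adjacent sectors; when no candidate satisfies it (or a sector is
empty) the trace terminates in that direction.  A hard stop at +-120 degrees
guards against wrap-around; anthropometrically the breast base never spans
more than that about RP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .candidates import CandidateSet
from .curvature import CurvatureField
from .errors import ContourError
from .refpoint import ReferencePoint

log = logging.getLogger(__name__)

__all__ = [
    "SectorPartition",
    "ContourResult",
    "SplineContour",
    "compute_angles",
    "find_point_M",
    "find_intermediate_point",
    "extend_contour",
    "fit_spline",
    "verify_chain",
]

DEFAULT_SECTOR_DEG = 5.0
DEFAULT_RADIUS_MM = 10.0
MAX_ANGLE_DEG = 120.0  # hard stop for extension in each direction


@dataclass
class SectorPartition:
    """Angles and sector ids of the candidate points on one side."""

    rp: ReferencePoint
    vertex_indices: np.ndarray  # candidate vertex ids, sorted by angle
    theta: np.ndarray  # degrees in (-180, 180], same order
    sector: np.ndarray  # sector id per candidate, same order
    sector_deg: float = DEFAULT_SECTOR_DEG

    def in_sector(self, k: int) -> np.ndarray:
        """Positions (into the sorted arrays) of candidates in sector k."""
        return np.nonzero(self.sector == k)[0]


@dataclass
class ContourResult:
    """Ordered detected contour vertices for one breast."""

    vertex_indices: np.ndarray  # ordered by ascending theta
    points: np.ndarray  # (k, 3) positions, same order
    sectors: np.ndarray  # sector id per detected point
    intermediate_index: int  # position of the intermediate point in the order
    point_m_vertex: int  # vertex id of point M
    rp: ReferencePoint = None
    termination: dict = field(default_factory=dict)  # direction -> reason

    def __len__(self):
        return len(self.vertex_indices)

    @property
    def endpoints(self) -> np.ndarray:
        return self.points[[0, -1]]


@dataclass
class SplineContour:
    """Natural cubic spline through detected points over chord length."""

    knots: np.ndarray  # (k, 3)
    parameter: np.ndarray  # strictly increasing chord-length parameter
    samples: np.ndarray  # (n_samples, 3) evenly spaced in parameter
    spline: CubicSpline


def compute_angles(
    candidates: CandidateSet,
    rp: ReferencePoint,
    side_vertices: np.ndarray | None = None,
    sector_deg: float = DEFAULT_SECTOR_DEG,
) -> SectorPartition:
    """Angle about RP (v1 along -y) for each candidate; sorted by angle."""
    idx = candidates.indices
    if side_vertices is not None:
        idx = np.intersect1d(idx, side_vertices)
    if len(idx) == 0:
        raise ContourError(f"{rp.side}: no candidate points on this side")
    pts = candidates.field.mesh.vertices[idx]
    dx = pts[:, 0] - rp.x
    dy = pts[:, 1] - rp.y
    norm = np.hypot(dx, dy)
    coincident = norm == 0
    if np.any(coincident):
        log.warning(
            "%s: %d candidates coincide with RP in (x, y); theta set to 0",
            rp.side,
            int(coincident.sum()),
        )
        norm[coincident] = 1.0
    cos_t = np.clip(-dy / norm, -1.0, 1.0)
    sign = np.where(dx < 0, -1.0, 1.0)  # sign(0) treated as +1
    theta = sign * np.degrees(np.arccos(cos_t))
    theta[coincident] = 0.0
    order = np.argsort(theta, kind="stable")
    sector = np.floor(theta[order] / sector_deg + 0.5).astype(int)
    return SectorPartition(
        rp=rp,
        vertex_indices=idx[order],
        theta=theta[order],
        sector=sector,
        sector_deg=sector_deg,
    )


def _noa(
    partition: SectorPartition,
    fld: CurvatureField,
    radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normal angle (max angle to one-ring normals of near candidates)."""
    pos0 = partition.in_sector(0)
    mesh = fld.mesh
    all_pts = mesh.vertices[partition.vertex_indices]
    tree = cKDTree(all_pts)
    noa = np.full(len(pos0), -np.inf)
    for i, p in enumerate(pos0):
        neigh = tree.query_ball_point(all_pts[p], radius)
        neigh = [j for j in neigh if j != p]
        if not neigh:
            continue
        n_p = fld.normal[partition.vertex_indices[p]]
        n_q = fld.normal[partition.vertex_indices[neigh]]
        cosang = np.clip(n_q @ n_p, -1.0, 1.0)
        noa[i] = np.degrees(np.arccos(cosang).max())
    return pos0, noa


def find_point_M(
    partition: SectorPartition,
    fld: CurvatureField,
    radius: float = DEFAULT_RADIUS_MM,
) -> int:
    """Candidate with the largest shape change in the sector below RP.

    Candidates with no neighbour within ``radius`` have undefined NOA and are
    skipped; ties go to the smaller vertex index.
    """
    pos0, noa = _noa(partition, fld, radius)
    if len(pos0) < 2:
        raise ContourError(
            f"{partition.rp.side}: no intermediate sector candidates "
            f"({len(pos0)} in sector 0)"
        )
    if not np.any(np.isfinite(noa)):
        raise ContourError(
            f"{partition.rp.side}: no candidate pair within {radius} mm in sector 0"
        )
    best = noa.max()
    tied = partition.vertex_indices[pos0[noa == best]]
    return int(tied.min())


def find_intermediate_point(
    m_vertex: int,
    candidates: CandidateSet,
    fld: CurvatureField,
    radius: float = DEFAULT_RADIUS_MM,
    side_vertices: np.ndarray | None = None,
) -> int:
    """Candidate within ``radius`` of M with minimal kmin (may be M itself)."""
    idx = candidates.indices
    if side_vertices is not None:
        idx = np.intersect1d(idx, side_vertices)
    pts = candidates.field.mesh.vertices[idx]
    m_pos = candidates.field.mesh.vertices[m_vertex]
    near = np.linalg.norm(pts - m_pos, axis=1) <= radius
    near_idx = idx[near]
    kmin = fld.kmin[near_idx]
    best = kmin.min()
    return int(near_idx[kmin == best].min())


def _arc_length_limit(rp: ReferencePoint, prev_point: np.ndarray,
                      sector_deg: float) -> float:
    """2L where L = (sector angle in rad) * R, R the planar RP distance."""
    r = float(np.hypot(prev_point[0] - rp.x, prev_point[1] - rp.y))
    return 2.0 * np.radians(sector_deg) * r


def extend_contour(
    intermediate_vertex: int,
    partition: SectorPartition,
    fld: CurvatureField,
    rp: ReferencePoint,
    max_angle_deg: float = MAX_ANGLE_DEG,
) -> ContourResult:
    """Extend from the intermediate point sector-by-sector in both directions."""
    mesh = fld.mesh
    vid = partition.vertex_indices
    where = np.nonzero(vid == intermediate_vertex)[0]
    if len(where) == 0:
        raise ContourError("intermediate point is not a candidate on this side")
    start_pos = int(where[0])
    start_sector = int(partition.sector[start_pos])
    max_sector = int(np.floor(max_angle_deg / partition.sector_deg))

    termination = {}
    chains = {}
    for direction in (+1, -1):
        key = "increasing" if direction > 0 else "decreasing"
        chain = []
        prev_point = mesh.vertices[intermediate_vertex]
        k = start_sector + direction
        while abs(k) <= max_sector:
            in_k = partition.in_sector(k)
            if len(in_k) == 0:
                termination[key] = "no-candidate"
                break
            pts = mesh.vertices[vid[in_k]]
            limit = _arc_length_limit(rp, prev_point, partition.sector_deg)
            dist = np.linalg.norm(pts - prev_point, axis=1)
            ok = dist < limit
            if not np.any(ok):
                termination[key] = "distance>2L"
                break
            kmin = fld.kmin[vid[in_k[ok]]]
            best = kmin.min()
            chosen = int(vid[in_k[ok]][kmin == best].min())
            chain.append((k, chosen))
            prev_point = mesh.vertices[chosen]
            k += direction
        else:
            termination[key] = "sector-range-exhausted"
        chains[direction] = chain

    seq = (
        [(k, v) for k, v in reversed(chains[-1])]
        + [(start_sector, intermediate_vertex)]
        + chains[+1]
    )
    sectors = np.array([k for k, _ in seq], dtype=int)
    vertices = np.array([v for _, v in seq], dtype=np.int64)
    intermediate_index = len(chains[-1])
    log.info(
        "%s: %d contour points over sectors [%d, %d]; termination %s",
        rp.side,
        len(vertices),
        sectors.min(),
        sectors.max(),
        termination,
    )
    return ContourResult(
        vertex_indices=vertices,
        points=mesh.vertices[vertices],
        sectors=sectors,
        intermediate_index=intermediate_index,
        point_m_vertex=-1,
        rp=rp,
        termination=termination,
    )


def fit_spline(result_or_points, n_samples: int = 200) -> SplineContour:
    """Natural cubic spline over cumulative chord length, sampled evenly.

    Accepts a ContourResult or a plain (k, 3) point array; needs >= 4 points.
    """
    pts = (
        result_or_points.points
        if isinstance(result_or_points, ContourResult)
        else np.asarray(result_or_points, dtype=float)
    )
    if len(pts) < 4:
        raise ContourError(f"contour too short: {len(pts)} points (need >= 4)")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ContourError("contour has consecutive duplicate points")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    spline = CubicSpline(t, pts, bc_type="natural")
    ts = np.linspace(0.0, t[-1], n_samples)
    return SplineContour(knots=pts, parameter=t, samples=spline(ts), spline=spline)


def verify_chain(result: ContourResult, sector_deg: float = DEFAULT_SECTOR_DEG
                 ) -> bool:
    """Independent post-hoc re-check of the 2L chain constraint.

    Walks outward from the intermediate point in both directions, recomputing
    L from the stored RP and the previous accepted point.
    """
    rp = result.rp
    i0 = result.intermediate_index
    for direction in (+1, -1):
        prev = result.points[i0]
        j = i0 + direction
        while 0 <= j < len(result.points):
            limit = _arc_length_limit(rp, prev, sector_deg)
            step = float(np.linalg.norm(result.points[j] - prev))
            if not step < limit:
                return False
            prev = result.points[j]
            j += direction
    return True
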