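"""End-to-end detection pipeline: curvature -> candidates -> RP -> contour -> LVP.

The library equivalent of running `ibc detect`: all stages with the published
defaults wired together, one result per breast side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

from . import candidates as cand_mod
from . import contour as contour_mod
from . import lvp as lvp_mod
from . import refpoint as rp_mod
from .curvature import principal_curvatures, shape_index
from .errors import HoleInContourRegionError, PipelineError
from .mesh_io import TriangleMesh, detect_holes

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SideResult", "DetectionResult", "detect"]


@dataclass
class PipelineConfig:
    """All tunable constants; the defaults are the published values."""

    block_size_mm: float = 5.0
    sector_deg: float = 5.0
    radius_mm: float = 10.0  # point-M / intermediate-point search radius
    use_2l_rule: bool = True
    lvp_cone_deg: float = 10.0
    lvp_cone_axis: str = "-y"  # or "+z"
    spline_samples: int = 200
    dice_thresholds: tuple = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
    side: str = "both"  # left / right / both
    max_angle_deg: float = 120.0
    check_holes: bool = True

    def validate(self) -> None:
        numeric = (
            self.block_size_mm,
            self.sector_deg,
            self.radius_mm,
            self.lvp_cone_deg,
            self.spline_samples,
            self.max_angle_deg,
        )
        if any(v <= 0 for v in numeric):
            raise PipelineError("all numeric config values must be positive")
        if self.side not in ("left", "right", "both"):
            raise PipelineError(f"side must be left/right/both, got {self.side!r}")
        if self.lvp_cone_axis not in ("-y", "+z"):
            raise PipelineError("lvp_cone_axis must be '-y' or '+z'")

    def as_dict(self) -> dict:
        return {
            "block_size_mm": self.block_size_mm,
            "sector_deg": self.sector_deg,
            "radius_mm": self.radius_mm,
            "use_2l_rule": self.use_2l_rule,
            "lvp_cone_deg": self.lvp_cone_deg,
            "lvp_cone_axis": self.lvp_cone_axis,
            "spline_samples": self.spline_samples,
            "dice_thresholds": list(self.dice_thresholds),
            "side": self.side,
            "max_angle_deg": self.max_angle_deg,
            "check_holes": self.check_holes,
        }


@dataclass
class SideResult:
    side: str
    rp: rp_mod.ReferencePoint
    contour: contour_mod.ContourResult
    spline: contour_mod.SplineContour
    lvp: lvp_mod.LowestVisiblePoint
    n_candidates: int


@dataclass
class DetectionResult:
    mesh: TriangleMesh
    config: PipelineConfig
    sides: dict = dc_field(default_factory=dict)  # side -> SideResult
    kmean: float = float("nan")
    n_candidates_total: int = 0

    def report(self) -> dict:
        rep = {
            "provenance": self.mesh.provenance,
            "n_vertices": self.mesh.n_vertices,
            "n_faces": self.mesh.n_faces,
            "kmean_per_mm": self.kmean,
            "n_candidates": self.n_candidates_total,
            "config": self.config.as_dict(),
            "sides": {},
        }
        for side, res in self.sides.items():
            rep["sides"][side] = {
                "status": "detected",
                "rp_xy_mm": [res.rp.x, res.rp.y],
                "rp_fallback_b_is_a": res.rp.fallback_b_is_a,
                "n_side_candidates": res.n_candidates,
                "n_contour_points": len(res.contour),
                "sector_range": [
                    int(res.contour.sectors.min()),
                    int(res.contour.sectors.max()),
                ],
                "termination": res.contour.termination,
                "lvp_present": res.lvp.present,
                "lvp_mm": (
                    None
                    if not res.lvp.present
                    else [float(v) for v in res.lvp.position]
                ),
            }
        return rep


def _check_holes(mesh: TriangleMesh, sides: dict) -> None:
    """Abort when an interior hole touches the lower half of a breast side.

    The outer rim (largest boundary loop) is expected for a cropped ROI;
    additional loops are holes.  A hole in the lower breast region makes the
    crease untraceable, so detection refuses to proceed there.
    """
    loops = detect_holes(mesh)
    if len(loops) <= 1:
        return
    for hole in loops[1:]:
        cx, cy = hole.centroid[0], hole.centroid[1]
        for name in ("left", "right"):
            pts = mesh.vertices[sides[name]]
            x0, x1 = pts[:, 0].min(), pts[:, 0].max()
            y0, y1 = pts[:, 1].min(), pts[:, 1].max()
            if x0 <= cx <= x1 and y0 <= cy <= (y0 + y1) / 2.0:
                raise HoleInContourRegionError(
                    f"hole in contour region: boundary loop of {len(hole)} "
                    f"vertices centred at ({cx:.1f}, {cy:.1f}) lies in the "
                    f"lower half of the {name} side"
                )
    log.warning(
        "%d interior holes outside the contour regions; proceeding", len(loops) - 1
    )


def detect(mesh: TriangleMesh, config: PipelineConfig | None = None
           ) -> DetectionResult:
    """Run the full contour + LVP detection on a validated ROI mesh."""
    config = config or PipelineConfig()
    config.validate()

    sides = rp_mod.split_sides(mesh)
    if config.check_holes:
        _check_holes(mesh, sides)

    fld = shape_index(principal_curvatures(mesh))
    spp = cand_mod.select_candidates(fld)

    result = DetectionResult(
        mesh=mesh,
        config=config,
        kmean=spp.kmean,
        n_candidates_total=len(spp),
    )
    wanted = ("left", "right") if config.side == "both" else (config.side,)
    for side in wanted:
        side_idx = sides[side]
        grid = rp_mod.build_block_grid(
            mesh, side_idx, fld, side, block_size=config.block_size_mm
        )
        rp = rp_mod.locate_reference_point(grid)
        partition = contour_mod.compute_angles(
            spp, rp, side_vertices=side_idx, sector_deg=config.sector_deg
        )
        m_vertex = contour_mod.find_point_M(partition, fld, radius=config.radius_mm)
        inter = contour_mod.find_intermediate_point(
            m_vertex, spp, fld, radius=config.radius_mm, side_vertices=side_idx
        )
        contour = contour_mod.extend_contour(
            inter, partition, fld, rp, max_angle_deg=config.max_angle_deg
        )
        contour.point_m_vertex = m_vertex
        spline = contour_mod.fit_spline(contour, n_samples=config.spline_samples)
        lvp = lvp_mod.detect_lvp(
            mesh, contour, cone_deg=config.lvp_cone_deg, axis=config.lvp_cone_axis
        )
        result.sides[side] = SideResult(
            side=side,
            rp=rp,
            contour=contour,
            spline=spline,
            lvp=lvp,
            n_candidates=len(partition.vertex_indices),
        )
    return result
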