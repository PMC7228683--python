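"""Candidate contour points: concave vertices with low minimum curvature.

A vertex joins the candidate set sPP when its shape index is negative
(concave) and its minimum principal curvature lies below the ROI-wide mean
of the minimum principal curvature (kmean).  The second condition removes
nearly flat regions where slight undulation makes kmax + kmin < 0 without any
real crease.  Scattered candidates away from the breast contour are expected
and are dealt with during contour tracing, not here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .curvature import CurvatureField
from .errors import CandidateError

log = logging.getLogger(__name__)

__all__ = ["CandidateSet", "select_candidates"]


@dataclass
class CandidateSet:
    """Vertex indices (sorted ascending) of possible contour points."""

    indices: np.ndarray  # sorted vertex ids into the parent mesh
    kmean: float  # ROI-wide mean of kmin used as the threshold (1/mm)
    field: CurvatureField

    def __len__(self):
        return len(self.indices)

    @property
    def positions(self) -> np.ndarray:
        return self.field.mesh.vertices[self.indices]


def select_candidates(
    field: CurvatureField, kmean: float | None = None
) -> CandidateSet:
    """Select sPP = {p : S(p) < 0 and kmin(p) < kmean}.

    kmean is the mean of kmin over all non-rim ROI vertices, and rim
    (boundary) vertices are not eligible as candidates either: the ROI crop
    leaves an artificial open border whose truncated one-rings produce
    arbitrarily strong spurious concavity, which would otherwise be traced
    as a fake crease.  kmean can be overridden for diagnostics; lowering it
    can only shrink the set.
    """
    if field.S is None:
        raise CandidateError("shape index not populated; call shape_index() first")
    interior = ~field.is_boundary
    if not np.any(interior):
        interior = np.ones(len(field.kmin), dtype=bool)
    if kmean is None:
        kmean = float(field.kmin[interior].mean())
    mask = interior & (field.S < 0) & (field.kmin < kmean)
    indices = np.nonzero(mask)[0]
    if len(indices) == 0:
        raise CandidateError(
            "no concave candidates (degenerate or non-torso input): "
            f"kmean={kmean:.6g}/mm"
        )
    frac = len(indices) / len(field.kmin)
    log.info(
        "sPP: %d candidates (%.1f%% of ROI vertices), kmean=%.5g/mm",
        len(indices),
        100 * frac,
        kmean,
    )
    return CandidateSet(indices=indices, kmean=kmean, field=field)
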