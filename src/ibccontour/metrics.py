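"""Contour agreement: symmetric average distance and threshold dice.

Two contours A and B are first length-normalised by cubic-spline resampling
to the same number of points (default 200).  The average distance is

    ave_d = ( sum_i d(A_i) + sum_j d(B_j) ) / (|A| + |B|) ,

where d(A_i) is the Euclidean distance from A_i to the closest point of B
(and symmetrically for B_j).  The dice coefficient at threshold t is the
fraction of points of both sets whose nearest-other-contour distance is
strictly less than t:

    Dc(t) = num / (|A| + |B|),  num = #{ points with d < t } .

Dc is non-decreasing in t and equals 1 when the contours coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .contour import SplineContour, fit_spline
from .errors import MetricsError
from .mesh_io import ContourAnnotation

__all__ = [
    "EvaluationReport",
    "resample_contour",
    "average_distance",
    "dice_coefficient",
    "evaluate_contours",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)  # mm
DEFAULT_SAMPLES = 200


@dataclass
class EvaluationReport:
    """Agreement between a detected and a reference contour."""

    ave_d: float  # mm
    dice: dict  # threshold (mm) -> Dc in [0, 1]
    n_samples: int
    contour_a: str = "detected"
    contour_b: str = "reference"
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "contour_a": self.contour_a,
            "contour_b": self.contour_b,
            "n_samples": self.n_samples,
            "ave_d_mm": self.ave_d,
            "dice": {f"{t:g}": v for t, v in self.dice.items()},
            **self.extras,
        }


def resample_contour(contour, n: int = DEFAULT_SAMPLES) -> np.ndarray:
    """n points evenly spaced in chord-length parameter along the contour.

    Accepts a ContourAnnotation, a SplineContour, or a raw (k, 3) array with
    at least 4 points.
    """
    if isinstance(contour, SplineContour):
        spline, t_end = contour.spline, contour.parameter[-1]
        return spline(np.linspace(0.0, t_end, n))
    pts = contour.points if isinstance(contour, ContourAnnotation) else contour
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 4:
        raise MetricsError(f"contour too short: {len(pts)} points (need >= 4)")
    sc = fit_spline(pts, n_samples=n)
    return sc.samples


def _nearest_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cKDTree(b).query(a)[0]


def average_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean nearest-point distance between two point sets (mm)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise MetricsError("average_distance: empty point set")
    d_ab = _nearest_distances(a, b)
    d_ba = _nearest_distances(b, a)
    return float((d_ab.sum() + d_ba.sum()) / (len(a) + len(b)))


def dice_coefficient(a: np.ndarray, b: np.ndarray, threshold: float) -> float:
    """Fraction of points of both sets strictly closer than ``threshold``."""
    if threshold <= 0:
        raise MetricsError(f"threshold must be positive, got {threshold}")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise MetricsError("dice_coefficient: empty point set")
    num = int((_nearest_distances(a, b) < threshold).sum()) + int(
        (_nearest_distances(b, a) < threshold).sum()
    )
    return num / (len(a) + len(b))


def evaluate_contours(
    detected,
    reference,
    thresholds=DEFAULT_THRESHOLDS,
    n_samples: int = DEFAULT_SAMPLES,
    names=("detected", "reference"),
) -> EvaluationReport:
    """Resample both contours and report ave_d plus Dc per threshold."""
    a = resample_contour(detected, n_samples)
    b = resample_contour(reference, n_samples)
    return EvaluationReport(
        ave_d=average_distance(a, b),
        dice={float(t): dice_coefficient(a, b, t) for t in thresholds},
        n_samples=n_samples,
        contour_a=names[0],
        contour_b=names[1],
    )
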