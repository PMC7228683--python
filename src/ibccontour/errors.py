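"""Exception hierarchy for the contour-detection pipeline.

Every stage raises a subclass of :class:`PipelineError` so callers (and the
CLI) can report which stage failed and why.
"""


class PipelineError(Exception):
    """Base class for all pipeline failures."""

    stage = "pipeline"


class MeshFormatError(PipelineError):
    """The input file is not a valid triangle mesh of the declared format."""

    stage = "mesh_io"


class RoiError(PipelineError):
    """ROI cropping produced an empty or unusable mesh."""

    stage = "mesh_io"


class HoleInContourRegionError(PipelineError):
    """A mesh hole lies inside the lower breast region; detection aborts."""

    stage = "mesh_io"


class CurvatureError(PipelineError):
    stage = "curvature"


class CandidateError(PipelineError):
    """No concave candidate points -- degenerate or non-torso input."""

    stage = "candidates"


class SideError(PipelineError):
    """A torso half has too few vertices to analyse."""

    stage = "refpoint"


class ContourError(PipelineError):
    stage = "contour"


class MetricsError(PipelineError):
    stage = "metrics"


class ValidationError(PipelineError):
    """Invalid synthetic-generator parameters."""

    stage = "synthetic"
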