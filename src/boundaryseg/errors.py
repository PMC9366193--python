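"""Exception hierarchy for boundaryseg.

Every stage of the pipeline raises a typed error so callers (and the CLI)
can distinguish degenerate inputs from programming mistakes.
"""


class BoundarySegError(Exception):
    """Base class for all boundaryseg errors."""


class DegenerateInputError(BoundarySegError):
    """Input carries no usable signal (e.g. a constant image)."""


class EmptyMaskError(BoundarySegError):
    """A binary mask with no foreground where foreground is required."""


class OpenContourError(BoundarySegError):
    """No closed boundary loop could be traced.

    Attributes
    ----------
    n_endpoints : int
        Number of curve endpoints (pixels with fewer than two neighbours)
        found in the edge raster.
    """

    def __init__(self, n_endpoints: int):
        self.n_endpoints = int(n_endpoints)
        super().__init__(
            f"no closed contour loop found ({self.n_endpoints} open endpoint(s))"
        )


class SalientSelectionError(BoundarySegError):
    """Contour too degenerate (collinear / too few points) for salient-point seeding."""


class MembershipError(BoundarySegError):
    """A point that must lie on the contour does not."""


class DegeneratePairError(BoundarySegError):
    """Two coincident points where a direction is required."""


class ShapeMismatchError(BoundarySegError):
    """Two rasters that must share a shape do not."""


class OutOfBoundsError(BoundarySegError):
    """A coordinate falls outside the raster."""


class UndefinedMetricError(BoundarySegError):
    """Metric denominator is empty (e.g. IOU of two empty masks)."""


class DegeneratePolygonError(BoundarySegError):
    """Fewer than three key points, or zero-area polygon."""


class ConfigError(BoundarySegError):
    """Invalid network / training / phantom configuration."""


class DataError(BoundarySegError):
    """Empty or inconsistent dataset."""


class TrainingError(BoundarySegError):
    """Training diverged (non-finite loss)."""

    def __init__(self, message: str, epoch: int | None = None):
        self.epoch = epoch
        super().__init__(message)


class PipelineStageError(BoundarySegError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
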