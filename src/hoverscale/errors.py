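"""Exception hierarchy shared across the package."""


class HoverscaleError(Exception):
    """Base class for package errors."""


class InvalidParameterError(HoverscaleError, ValueError):
    """A numeric or enum parameter violates its precondition."""


class GeometryError(HoverscaleError):
    """A wing outline is degenerate, self-intersecting, or otherwise unusable."""


class OutlineGenerationError(GeometryError):
    """Requested parameters cannot produce a valid closed outline."""


class UndersamplingError(InvalidParameterError):
    """A time series is sampled too coarsely for the requested wingbeat frequency."""


class UnderdeterminedFitError(HoverscaleError):
    """Fewer samples than free coefficients in a least-squares fit."""


class AlignmentError(HoverscaleError):
    """Timebases or landmark configurations cannot be aligned."""


class LabelMismatchError(HoverscaleError, KeyError):
    """Species labels in a trait table do not match the tree tips."""


class TreeDegeneracyError(HoverscaleError):
    """The phylogenetic covariance matrix is singular (e.g. zero-length splits)."""


class DegenerateTraitError(HoverscaleError, ValueError):
    """A trait has no variance where variance is required."""


class CollinearityWarning(UserWarning):
    """Predictors in a multiple regression are (near-)collinear."""


class StageError(HoverscaleError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str, record: str | None = None):
        self.stage = stage
        self.record = record
        detail = f"[{stage}] {message}"
        if record is not None:
            detail += f" (record: {record})"
        super().__init__(detail)
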