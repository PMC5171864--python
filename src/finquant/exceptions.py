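"""Exception hierarchy for finquant.

Errors are split into annotation/data problems (bad inputs) and
analysis problems (inputs valid but the measurement is undefined),
so batch pipelines can record per-record failures and continue.
"""


class FinquantError(Exception):
    """Base class for all finquant errors."""


class InvalidAnnotationError(FinquantError):
    """Amputation-plane or calibration annotation is unusable."""


class EmptyRegenerateError(FinquantError):
    """No tissue component found distal to the amputation plane."""


class EmptyPolygonError(FinquantError):
    """No mineral components distal to the plane; EMA is undefined (0)."""


class MissingRayError(FinquantError):
    """No ray yielded a measurable width at its first proximal joint."""


class MissingCorrectionError(FinquantError):
    """A corrected ratio was requested but its correcting factor is absent."""


class InvalidSpecimenError(FinquantError):
    """A specimen-level quantity (e.g. stump width) is degenerate."""


class SingularFitError(FinquantError):
    """A regression design matrix is rank deficient."""


class NoBreakpointError(FinquantError):
    """No candidate breakpoint leaves >= 3 supporting points per segment."""


class WindowTooSparseError(FinquantError):
    """Too few points inside the screening time window to fit a curve."""


class UnderpoweredError(FinquantError):
    """A group comparison was requested with fewer than 3 points per group."""


class UndefinedStatisticError(FinquantError):
    """A statistic is undefined for the given data (e.g. constant series)."""


class ExposureMismatchError(FinquantError):
    """Records with different acquisition exposures cannot be pooled."""
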