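"""Exception hierarchy for atcurve.

Every error raised on a user-facing path derives from :class:`ATCurveError`,
so pipeline drivers can catch one type and report the failing stage.
"""


class ATCurveError(Exception):
    """Base class for all atcurve errors."""


class InvalidInputError(ATCurveError):
    """Structurally invalid input (wrong shape, too few points, mismatched counts)."""


class InvalidParameterError(ATCurveError):
    """A parameter value outside its valid domain."""


class DataGapError(ATCurveError):
    """Non-finite coordinates encountered where a gap is not allowed.

    Carries ``frames``: the offending frame indices, when known.
    """

    def __init__(self, message, frames=None):
        super().__init__(message)
        self.frames = frames


class InvalidSubsetError(ATCurveError):
    """Foil-marker subset indices are unsorted, duplicated, or out of range."""


class DegenerateConfigurationError(ATCurveError):
    """Geometric configuration does not determine a solution (e.g. collinear points)."""


class DetectionFailureError(ATCurveError):
    """Image-analysis detection failed on too large a fraction of the input."""


class PoseUnavailableError(ATCurveError):
    """No probe pose available for the requested frame."""


class InvalidSyncError(ATCurveError):
    """Stream synchronization trigger lies outside the recording."""


class NoEventsError(ATCurveError):
    """No qualifying gait events found in the series."""


class AmbiguousEventsError(ATCurveError):
    """Gait-event candidates cannot be paired into strides unambiguously."""


class InvalidSegmentationError(ATCurveError):
    """Phase segmentation inconsistent with the data (e.g. an empty phase)."""


class InsufficientDataError(ATCurveError):
    """Not enough data points for the requested analysis."""


class TooFewMarkersError(ATCurveError):
    """Simulated geometry cannot accommodate even one interior foil marker."""


class ParseError(ATCurveError):
    """Malformed input file; message names the offending line or frame."""


class UnitError(ATCurveError):
    """Unknown or unsupported physical units in an input file."""
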