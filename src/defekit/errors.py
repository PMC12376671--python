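"""Exception hierarchy for stream extraction, fitting and scoring failures."""


class DefekitError(Exception):
    """Base class for all package-specific errors."""


class TimestampParseError(DefekitError, ValueError):
    """Frame filename does not encode a valid hhmmss.ssss time of day."""


class NoDefecationError(DefekitError):
    """Stream never enters the stool state / has no stool detections."""


class NoCleansingError(DefekitError):
    """Stream has no toilet-paper frames, so cleansing cannot be located."""


class TruncatedStreamError(DefekitError):
    """Stream ends before the bowl returns to the clean state."""


class IncompleteDropError(DefekitError):
    """A drop episode lacks either its dropping or its dropped detection."""


class StreamOrderError(DefekitError):
    """Detections occur in a physically impossible temporal order."""


class InsufficientSampleError(DefekitError):
    """A statistical routine received fewer observations than it requires."""


class UndefinedScoreError(DefekitError):
    """Silhouette score is undefined (fewer than two distinct labels)."""


class DegenerateFitError(DefekitError):
    """Model fit is impossible (constant regressor, too few points, ...)."""
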