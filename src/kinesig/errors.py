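"""Exception hierarchy shared across the package."""


class KinesigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KinesigError):
    """A file does not conform to the expected dialect (TRC/MOT/manifest)."""


class UnitError(FormatError):
    """Units declared in a file header are not supported."""


class SchemaError(FormatError):
    """Structural problem: duplicate columns, unknown labels, dangling refs."""


class DataError(KinesigError):
    """Well-formed file with invalid content (non-monotonic time, long gaps)."""


class ConfigurationError(KinesigError):
    """Required markers/angles missing, or invalid analysis configuration."""


class InsufficientGaitError(KinesigError):
    """Too few gait events to compute stride-level quantities."""


class EventDetectionError(KinesigError):
    """Detected events violate alternation/phase invariants."""


class SegmentationError(KinesigError):
    """Task repetitions could not be segmented from the COM trajectory."""


class FeatureError(KinesigError):
    """A feature could not be computed from an otherwise valid trial."""


class ConflictError(KinesigError):
    """Duplicate trial for the same (participant, activity, session)."""


class StratificationError(KinesigError):
    """A cross-validation fold cannot be stratified with the data given."""


class DegenerateFitError(KinesigError):
    """A regression fold has zero variance in its predictor."""
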