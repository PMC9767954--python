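"""Exception hierarchy.

Every error raised by the package derives from :class:`HandScreenError`, so
callers can distinguish pipeline failures from programming errors.
"""


class HandScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(HandScreenError):
    """A file does not conform to the documented column/field schema."""


class ValidationError(HandScreenError):
    """A record violates a structural invariant (point count, finiteness,
    uniqueness of the record key)."""


class DegenerateGeometryError(HandScreenError):
    """A geometric quantity is undefined for the given landmarks
    (zero-length segment, collinear palm plane, ...)."""


class CalibrationError(HandScreenError):
    """ROC/threshold calibration is impossible (e.g. single-class input)."""


class FitError(HandScreenError):
    """A model cannot be fitted on the given training data."""


class PredictionError(HandScreenError):
    """Prediction requested with missing features or mismatched gesture."""


class EvaluationError(HandScreenError):
    """Inconsistent inputs to an evaluation routine."""


class GenerationError(HandScreenError):
    """The synthetic generator cannot realize the requested configuration."""


class CapabilityError(HandScreenError):
    """An optional capability (e.g. an image tracker adapter) is absent."""
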