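"""Named exception types so callers can distinguish failure modes."""


class ErgsurfError(Exception):
    """Base class for package errors."""


class SchemaError(ErgsurfError):
    """Input table is missing required columns."""


class NonNumericError(ErgsurfError):
    """A numeric column contains non-numeric or missing values."""


class NonPositiveFlashError(ErgsurfError):
    """Flash strength must be strictly positive (Td.s)."""


class DuplicateKeyError(ErgsurfError):
    """Duplicated (subject, eye, flash, time) observation keys."""


class NonMonotoneTimeError(ErgsurfError):
    """A (subject, eye, flash) series is not strictly increasing in time."""


class SingularModelError(ErgsurfError):
    """Penalized normal matrix is (numerically) singular."""


class SaturatedFitError(ErgsurfError):
    """Effective degrees of freedom reached the sample size (GCV undefined)."""


class PredictionRangeError(ErgsurfError):
    """Prediction requested outside the fitted (t, FS) rectangle."""


class OptimizationError(ErgsurfError):
    """Smoothing-parameter search found no finite criterion value."""


class ModelFormatError(ErgsurfError):
    """Serialized model file is malformed or has an unsupported version."""
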