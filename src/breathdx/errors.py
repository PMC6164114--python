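"""Exception hierarchy shared across the pipeline stages."""


class BreathdxError(Exception):
    """Base class for all breathdx errors."""


class ConfigurationError(BreathdxError):
    """Invalid simulation or run configuration."""


class DataError(BreathdxError):
    """Malformed or physically impossible sensor data."""


class QualityError(DataError):
    """A subject fails replicate quality control; the message lists the cause."""


class NormalizationError(DataError):
    """A sample cannot be vector-normalized (all-zero row)."""


class DegenerateFeatureError(DataError):
    """A sensor column has zero variance and cannot be autoscaled."""


class LeakageError(BreathdxError):
    """Calibration and external-validation subjects overlap."""
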