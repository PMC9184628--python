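"""Exception hierarchy shared across the package."""


class HostDepleteError(Exception):
    """Base class for all package errors."""


class ParseError(HostDepleteError):
    """A sequence record could not be parsed."""


class UsageError(HostDepleteError):
    """Invalid user-facing arguments (unknown format token etc.)."""


class ConfigError(HostDepleteError):
    """An invalid configuration value or combination."""


class ConsistencyError(HostDepleteError):
    """Record ids and reads do not line up."""


class LengthError(HostDepleteError):
    """An input length outside the model's supported range."""


class CalibrationError(HostDepleteError):
    """Threshold calibration is impossible (e.g. single-class slice)."""


class ModelLoadError(HostDepleteError):
    """A model checkpoint could not be loaded."""


class MetricError(HostDepleteError):
    """A metric is undefined for the given input."""
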