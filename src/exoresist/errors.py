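"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems exit 2,
insufficient data exits 3.
"""


class ExoResistError(Exception):
    """Base class for all package errors."""


class ValidationError(ExoResistError, ValueError):
    """Invalid argument, malformed file, or violated schema."""


class CalibrationError(ExoResistError, RuntimeError):
    """Peak-moment calibration could not be completed (e.g. no stance)."""


class ConfigurationError(ExoResistError, ValueError):
    """Inconsistent configuration, e.g. calibration limbs not matching a trial."""


class InsufficientDataError(ExoResistError, ValueError):
    """Not enough data for the requested computation (e.g. series < window)."""
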