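"""Exception types shared across the package."""


class GcsfCeaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GcsfCeaError):
    """A scenario file is missing a required key or cannot be parsed."""


class ValidationError(GcsfCeaError, ValueError):
    """A parameter value violates a documented invariant.

    The message always names the offending field and the violated bound.
    """


class CalibrationError(GcsfCeaError):
    """A numerical calibration (risk root or cost solve) failed."""
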