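"""Exception hierarchy shared across the package."""


class PPAdoptError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PPAdoptError):
    """A parameter or configuration value is invalid; the message names the field."""


class CalibrationError(PPAdoptError):
    """Utility-coefficient calibration is infeasible for the requested inputs."""


class InvariantViolationError(PPAdoptError):
    """An internal consistency check (stock conservation, bounds) failed."""
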