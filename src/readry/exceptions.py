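"""Exception hierarchy for the readry package."""


class ReadryError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ReadryError, ValueError):
    """A physical quantity lies outside the validity range of a correlation."""


class ConfigurationError(ReadryError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class InputError(ReadryError, ValueError):
    """A measured input series is malformed."""


class CalibrationError(ReadryError, RuntimeError):
    """The inverse pipeline cannot produce a fit from the given data."""


class SimulationError(ReadryError, RuntimeError):
    """The ODE integration failed; carries the last successfully computed state."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class TargetNotReachedError(ReadryError, RuntimeError):
    """A moisture target was never crossed; carries the closest approach."""

    def __init__(self, message, final_X=None, final_t=None):
        super().__init__(message)
        self.final_X = final_X
        self.final_t = final_t
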