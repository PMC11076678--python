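"""Exception types shared across the package."""


class ThalabetaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThalabetaError, ValueError):
    """A parameter or configuration value violates its documented range."""


class InvalidStateError(ThalabetaError, ValueError):
    """A state vector or input contains non-finite values."""


class IntegrationError(ThalabetaError, RuntimeError):
    """The ODE integration diverged.

    Attributes
    ----------
    time : float
        Simulated time (s) at which the blow-up was detected.
    repeat_index : int or None
        Index of the noise realization that failed, when applicable.
    """

    def __init__(self, message, time=None, repeat_index=None):
        super().__init__(message)
        self.time = time
        self.repeat_index = repeat_index
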