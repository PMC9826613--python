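"""Exception hierarchy shared across the package."""


class ReefstressError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ReefstressError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class EmptyInputError(ReefstressError, ValueError):
    """An input file or sequence contained no usable records."""


class InsufficientDataError(ReefstressError, ValueError):
    """Too few observations to compute the requested quantity."""


class DegenerateDataError(ReefstressError, ValueError):
    """Data degenerate for the requested test (e.g. all paired differences zero)."""


class EmptyPairingError(ReefstressError, ValueError):
    """Year alignment produced no paired days."""


class DomainError(ReefstressError, ValueError):
    """An argument lies outside the mathematical domain of the operation."""


class ConvergenceError(ReefstressError, RuntimeError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class NotApplicableError(ReefstressError, ValueError):
    """The requested diagnostic does not apply to this model/data shape."""
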