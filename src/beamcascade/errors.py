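"""Exception types raised across the package."""


class BeamcascadeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BeamcascadeError):
    """An unknown registry key or invalid configuration value."""


class DomainError(BeamcascadeError, ValueError):
    """A geometric precondition is violated (e.g. a source outside the conductor)."""


class DegenerateInputError(BeamcascadeError, ValueError):
    """An input is degenerate for the requested operation (zero gain, zero variance)."""


class ConstructionError(BeamcascadeError):
    """A constrained geometric construction could not be satisfied."""


class InversionError(BeamcascadeError):
    """The sample covariance is numerically singular.

    Raised when filters are requested from an ill-conditioned covariance while
    diagonal loading is disabled; the message points at the loading flag.
    """
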