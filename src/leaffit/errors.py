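"""Exception hierarchy shared across the package."""


class LeaffitError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(LeaffitError, ValueError):
    """Model parameters or evaluation arguments violate their domain."""


class InputDataError(LeaffitError, ValueError):
    """A measurement series or table is unusable as supplied."""


class DegenerateSeriesError(InputDataError):
    """The series carries no growth signal (e.g. constant length)."""


class ConfigurationError(LeaffitError, ValueError):
    """An option value (family tag, config key) is not recognised."""
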