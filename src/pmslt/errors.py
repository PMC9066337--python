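"""Exception types shared across the package."""


class PMSLTError(Exception):
    """Base class for all package errors."""


class DomainError(PMSLTError, ValueError):
    """An argument lies outside its mathematically valid domain."""


class ConfigurationError(PMSLTError, ValueError):
    """A configuration value is invalid; the message names the field."""


class NumericalStabilityError(PMSLTError, RuntimeError):
    """A discrete annual step produced an invalid compartment.

    Raised when transition rates are too large for a one-year cycle; the
    remedy is sub-annual stepping or smaller rates.
    """


class ReportingError(PMSLTError, ValueError):
    """A report could not be assembled (e.g. a missing denominator)."""
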