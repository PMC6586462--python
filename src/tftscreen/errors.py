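"""Exception hierarchy for tftscreen.

All package-specific failures derive from :class:`TFTScreenError` so callers
can catch one base class at pipeline boundaries.
"""


class TFTScreenError(Exception):
    """Base class for all tftscreen errors."""


class FormatError(TFTScreenError):
    """A delimited-text input violates the expected schema or value domain."""


class IncompleteDataError(TFTScreenError):
    """A measurement table does not cover every layout position."""


class QCError(TFTScreenError):
    """Quality control cannot be applied (e.g. a plate with all-zero sizes)."""


class DomainError(TFTScreenError, ValueError):
    """A numeric argument lies outside the mathematically attainable domain."""


class InvalidParameterError(TFTScreenError, ValueError):
    """A model parameter set is invalid (e.g. all rates zero)."""


class DegenerateDistributionError(TFTScreenError):
    """A reference distribution has zero spread; z-scores are undefined."""


class ConfigError(TFTScreenError):
    """A run or module configuration is inconsistent or incomplete."""
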