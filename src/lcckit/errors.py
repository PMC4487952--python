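"""Exception and warning types shared across the package.

``ValidationError`` marks invalid numeric or tabular input (CLI exit
code 2); ``ConfigurationError`` marks inconsistent configuration such as
an unmapped item or a missing factor (CLI exit code 3).
"""


class LCCError(Exception):
    """Base class for all package errors."""


class ValidationError(LCCError):
    """Invalid input data (bad value, missing year, malformed table)."""

    exit_code = 2


class ConfigurationError(LCCError):
    """Inconsistent configuration (unknown category, unmapped item)."""

    exit_code = 3


class DataQualityWarning(UserWarning):
    """Suspicious but usable data, e.g. a net-exporting consumption item."""


class DegenerateColumnWarning(UserWarning):
    """A constant indicator column that carries no ranking information."""
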