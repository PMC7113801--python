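"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericError -> 4.
"""


class WtteError(Exception):
    """Base class for all package errors."""


class ConfigError(WtteError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class DataError(WtteError, ValueError):
    """Input data violates a structural precondition."""


class NumericError(WtteError, ArithmeticError):
    """Numerical failure during optimisation (non-finite cost, etc.)."""
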