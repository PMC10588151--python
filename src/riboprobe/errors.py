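"""Exception hierarchy.

The CLI maps these onto distinct exit codes: configuration problems (bad
parameters, missing inputs) exit 2, data problems (malformed or inconsistent
input files) exit 3, anything else exits 4.
"""


class RiboprobeError(Exception):
    """Base class for all package errors."""


class ConfigError(RiboprobeError):
    """Invalid configuration or parameter values."""


class DataError(RiboprobeError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed."""


class ValidationError(DataError):
    """Parsed data violates a documented invariant."""


class ContractError(RiboprobeError):
    """An internal API was called with inputs violating its contract."""
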