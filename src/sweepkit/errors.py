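"""Exception hierarchy.

ConfigError and ContractError map onto the CLI exit codes 2 and 1
respectively; FormatError/DataError are raised while parsing or
validating input files and are treated as contract errors at the CLI
boundary.
"""


class SweepkitError(Exception):
    """Base class for all package errors."""


class FormatError(SweepkitError):
    """An input file violates its format (bad BED interval, VCF without GT...)."""


class ContractError(SweepkitError):
    """A documented precondition of an operation was violated."""


class ConfigError(SweepkitError):
    """Invalid configuration value (window <= 0, unknown key...)."""


class DataError(SweepkitError):
    """Inconsistent data content (reference mismatch, dangling parent...)."""


class SampleLookupError(SweepkitError, KeyError):
    """A requested sample or group is absent from the data."""
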