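"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4, anything else -> 1.
"""


class SharkCPUEError(Exception):
    """Base class for package errors."""


class ConfigError(SharkCPUEError):
    """Invalid configuration (bad parameter values, inconsistent schedule)."""


class DataError(SharkCPUEError):
    """Input tables violate a contract (e.g. catch with zero effort)."""


class ConvergenceError(SharkCPUEError):
    """A sampler or optimizer failed to meet its convergence contract."""
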