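"""Exception hierarchy shared across the package.

Each error class carries the process exit code the command-line layer maps
it to: 2 for configuration problems, 3 for data problems, 4 for network
problems.
"""


class SkinoraError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(SkinoraError):
    """Invalid configuration value or combination."""

    exit_code = 2


class DataError(SkinoraError):
    """Input data violates a documented contract."""

    exit_code = 3


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(DataError):
    """Parsed data violates an invariant (duplicates, dangling edges, ...)."""


class DesignError(DataError):
    """Sample design table is inconsistent with the expression data."""


class NetworkError(SkinoraError):
    """A remote resource could not be retrieved."""

    exit_code = 4
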