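"""Exception hierarchy.

ConfigError / DataError map onto the CLI exit codes 2 / 3; InvariantError
(exit 4) marks a violated internal consistency check, which indicates a bug
rather than bad input.
"""


class ConsplanError(Exception):
    """Base class for all package errors."""


class ConfigError(ConsplanError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ConsplanError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


class GridMismatchError(DataError):
    """Layers that must share a GridSpec do not."""


class GeometryError(DataError):
    """Invalid or degenerate geometry."""


class InvariantError(ConsplanError):
    """An internal cross-module consistency check failed (CLI exit code 4)."""
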