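"""Exception hierarchy.

``InputError`` (and subclasses) map to CLI exit code 2, ``ConfigError``
to exit code 3; everything else is a bug.
"""


class ParchscapeError(Exception):
    """Base class for all package errors."""


class InputError(ParchscapeError):
    """Bad or inconsistent user input (structures, tables, trajectories)."""


class ParseError(InputError):
    """Malformed structure file; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PartitionError(InputError):
    """DNA atom that matches no backbone/nucleobase template entry."""


class GeometryError(InputError):
    """Invalid or degenerate geometry (builders, methyl placement)."""


class ConfigError(ParchscapeError):
    """Invalid configuration value or unresolvable chain map."""
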