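"""Exception hierarchy.

All package errors derive from :class:`PolyQuantError` so callers (and the
CLI) can distinguish data problems (exit 1) from usage problems (exit 2,
handled by click).
"""


class PolyQuantError(Exception):
    """Base class for all polyquant errors."""


class InputError(PolyQuantError):
    """A referenced input file is missing or unreadable."""


class ParseError(PolyQuantError):
    """A data line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ValidationError(PolyQuantError, ValueError):
    """A parameter or object violates its invariants."""


class DegenerateInputError(PolyQuantError):
    """Numerically degenerate input (e.g. zero or negative total area)."""


class FeatureNotFoundError(PolyQuantError):
    """No feature of the requested kind exists; lower the resolution
    half-window or pass a raw index instead of snapping."""


class NoSeedsError(PolyQuantError):
    """Peak seeding produced no candidates; widen the region or adjust
    smoothing/resolution."""


class SessionError(PolyQuantError):
    """Session document problem (missing files, malformed structure)."""


class SchemaVersionError(SessionError):
    """Session schema_version is unknown; sessions are never silently
    migrated."""
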