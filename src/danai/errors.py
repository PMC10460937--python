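"""Exception hierarchy shared across the package."""


class DanaiError(Exception):
    """Base class for all package errors."""


class ParseError(DanaiError):
    """A text record could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StructuralError(DanaiError):
    """Input is syntactically readable but structurally inconsistent."""


class GeometryError(DanaiError):
    """Degenerate cell or a cutoff incompatible with the minimum-image contract."""


class NotationSyntaxError(DanaiError):
    """A DANAI statement violates the grammar.

    Carries the 0-based character offset of the offending token.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"offset {offset}: {message}"
        super().__init__(message)


class ClassificationError(DanaiError):
    """An edge or species falls outside the configured macro-class tag set."""


class UnsupportedPatternError(DanaiError):
    """Pattern topology outside the supported L2/L3/R3/J4/J5 family."""


class GenerationError(DanaiError):
    """Synthetic configuration could not be generated (e.g. packing failure)."""

    def __init__(self, message: str, achieved: int | None = None):
        self.achieved = achieved
        super().__init__(message)


class OracleSizeError(DanaiError):
    """Graph too large for the exhaustive brute-force census."""
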