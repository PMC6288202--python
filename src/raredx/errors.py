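"""Exception hierarchy shared across the package."""


class RaredxError(Exception):
    """Base class for all package errors."""


class InputError(RaredxError):
    """Invalid user-supplied values (empty sets, bad rates, unknown modes)."""


class ParseError(RaredxError):
    """Malformed input file content; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StructuralError(RaredxError):
    """Ontology structure violations: cycles, dangling edges."""


class LookupError_(RaredxError):
    """Unknown term or disease identifier."""


class ConsistencyError(RaredxError):
    """Artifacts built from mismatched inputs combined in one call."""


class TrainingError(RaredxError):
    """No ensemble member could be trained."""
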