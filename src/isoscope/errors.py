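"""Exception hierarchy shared across the package."""


class IsoscopeError(Exception):
    """Base class for all package-specific failures."""


class ParseError(IsoscopeError, ValueError):
    """A malformed input record.

    Parameters
    ----------
    message:
        Human-readable description of the defect.
    line_number:
        1-based line number in the offending stream, when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class AnnotationError(IsoscopeError, ValueError):
    """Inconsistent or incomplete annotation (e.g. one transcript, two genes)."""


class EnrichmentError(IsoscopeError, ValueError):
    """Degenerate enrichment input (empty intersection, set covering the list)."""


class PlotModelError(IsoscopeError, ValueError):
    """A plot model cannot be built or rendered from the given inputs."""
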