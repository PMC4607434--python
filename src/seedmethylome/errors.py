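"""Exception types shared across the package."""


class SeedMethylomeError(Exception):
    """Base class for package-specific errors."""


class OutOfBoundsError(SeedMethylomeError, IndexError):
    """A genomic position lies outside its contig."""


class NotACytosineError(SeedMethylomeError, ValueError):
    """The referenced base is not a cytosine on the requested strand."""


class UndefinedValueError(SeedMethylomeError, ValueError):
    """A statistic is undefined for the given input (e.g. zero coverage)."""


class AlignmentError(SeedMethylomeError, ValueError):
    """Two window/profile streams do not share the same tiling or binning."""


class ParseError(SeedMethylomeError, ValueError):
    """A line of an input file could not be parsed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class SizingError(SeedMethylomeError, ValueError):
    """A simulated genome is too small for the requested feature layout."""
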