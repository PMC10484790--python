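"""Exception hierarchy shared across the package."""


class PlmvepError(Exception):
    """Base class for all package errors."""


class ValidationError(PlmvepError, ValueError):
    """Invalid input value or inconsistent parameter combination."""


class SequenceLengthError(ValidationError):
    """Sequence exceeds the backend input-length limit; callers should tile."""


class NonCanonicalResidueError(ValidationError):
    """Sequence contains a residue outside the 20-letter canonical alphabet."""

    def __init__(self, sequence_id: str, position: int, residue: str):
        self.sequence_id = sequence_id
        self.position = position
        self.residue = residue
        super().__init__(
            f"non-canonical residue {residue!r} at position {position} "
            f"of sequence {sequence_id!r}"
        )


class ReferenceMismatchError(ValidationError):
    """Variant reference residue disagrees with the sequence."""

    def __init__(self, sequence_id: str, position: int, expected: str, observed: str):
        self.sequence_id = sequence_id
        self.position = position
        self.expected = expected
        self.observed = observed
        super().__init__(
            f"reference mismatch in {sequence_id!r} at position {position}: "
            f"variant says {expected!r}, sequence has {observed!r}"
        )


class UnsupportedVariantError(ValidationError):
    """Variant kind or geometry outside supported scope (e.g. frameshift)."""


class VariantParseError(ValidationError):
    """Variant notation string could not be parsed."""


class DegenerateFitError(PlmvepError):
    """Distribution fit impossible on degenerate (e.g. constant) input."""
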