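"""Exception hierarchy for the annotation data model and its file formats.

All errors raised by this package derive from :class:`ProtAnnotError`, so
callers can catch a single base class at an application boundary while tests
and library code can assert on the specific failure mode.
"""


class ProtAnnotError(Exception):
    """Base class for all errors raised by protannot."""


class DuplicateIDError(ProtAnnotError):
    """A protein unique_ID was added twice under the strict duplicate policy."""


class AlphabetError(ProtAnnotError):
    """A sequence contains a character outside the configured amino-acid alphabet."""

    def __init__(self, character: str, position: int, unique_id: str = ""):
        self.character = character
        self.position = position
        self.unique_id = unique_id
        where = f" in protein '{unique_id}'" if unique_id else ""
        super().__init__(
            f"invalid character '{character}' at position {position}{where}"
        )


class BoundsError(ProtAnnotError):
    """A coordinate falls outside [1, sequence length]."""


class CoordinateOrderError(ProtAnnotError):
    """A region has start > stop (inverted coordinates)."""


class TrackLengthError(ProtAnnotError):
    """A track payload does not match its protein's sequence length."""

    def __init__(self, expected: int, actual: int, name: str = ""):
        self.expected = expected
        self.actual = actual
        self.name = name
        label = f" '{name}'" if name else ""
        super().__init__(
            f"track{label} length mismatch: expected {expected} values, got {actual}"
        )


class DuplicateTrackError(ProtAnnotError):
    """A track name is already in use on this protein."""


class MissingTrackError(ProtAnnotError):
    """A named track does not exist on this protein."""


class EmptyRegionError(ProtAnnotError):
    """An operation requiring at least one residue received an empty region."""


class EmptyInputError(ProtAnnotError):
    """An input file contains no records."""


class ParseError(ProtAnnotError):
    """A file could not be parsed as the expected format."""


class SpecError(ProtAnnotError):
    """A synthetic-proteome specification is internally inconsistent."""


class InsufficientDataError(ProtAnnotError):
    """Too few usable observations to compute the requested statistic."""
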