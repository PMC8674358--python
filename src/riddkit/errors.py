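"""Exception hierarchy shared across the toolkit."""


class RiddkitError(Exception):
    """Base class for all riddkit errors."""


class AlphabetError(RiddkitError):
    """A sequence contains a character outside the accepted alphabet."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(f"invalid character {char!r} at position {position}")


class FastaFormatError(RiddkitError):
    """Malformed FASTA input (empty file, duplicate ids, empty record)."""


class RangeError(RiddkitError):
    """A coordinate or boundary falls outside the valid range."""


class DegenerateInputError(RiddkitError):
    """Input is structurally valid but too degenerate for the operation."""


class InsufficientReplicationError(RiddkitError):
    """A design stratum has fewer replicates than the statistic requires."""


class IncompleteStatsError(RiddkitError):
    """A per-gene statistics table is missing required fields."""


class CoverageError(RiddkitError):
    """Too few gene-set members are present in the expression matrix."""


class GenerationError(RiddkitError):
    """A synthetic-data generator failed (e.g. rejection sampling exhausted)."""
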