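"""Sequence data model, alphabet normalization, and FASTA I/O.

All sequences are stored as uppercase RNA over ``{A, C, G, U, N}``, 5′→3′.
DNA input is accepted and silently converted (``T``→``U``): substrates are
RNAs but most constructs they derive from are cDNA. Coordinates are 0-based
with half-open intervals; a cleavage boundary ``b`` denotes the
inter-nucleotide bond between ``sequence[b-1]`` and ``sequence[b]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from riddkit.errors import AlphabetError, FastaFormatError

RNA_ALPHABET = frozenset("ACGUN")
_VALID_INPUT = frozenset("ACGTUN")


def normalize_sequence(raw: str) -> str:
    """Normalize a raw sequence string to uppercase RNA.

    Uppercases, maps ``T``→``U``, keeps ``N``. Raises
    :class:`~riddkit.errors.AlphabetError` naming the first offending
    character and its position for anything outside ``{A,C,G,T,U,N}``
    (case-insensitive).
    """
    up = raw.upper()
    for i, ch in enumerate(up):
        if ch not in _VALID_INPUT:
            raise AlphabetError(ch, i)
    return up.replace("T", "U")


@dataclass(frozen=True)
class TranscriptRecord:
    """An identified 5′→3′ RNA sequence.

    ``sequence`` is normalized on construction; ``id`` must be non-empty
    and contain no whitespace.
    """

    id: str
    sequence: str
    description: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaFormatError(f"invalid transcript id {self.id!r}")
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: Union[str, Path]) -> List[TranscriptRecord]:
    """Read a (multi-record) FASTA file into normalized transcript records.

    Record ids are the first whitespace-delimited token of each header;
    order is preserved. Raises :class:`FastaFormatError` on an empty file,
    duplicate ids, or a record with an empty sequence.
    """
    records: List[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(TranscriptRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: Union[str, Path], width: int = 70) -> None:
    """Write transcript records to FASTA with lines folded at ``width``."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)
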