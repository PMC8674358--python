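"""Map cleavage-fragment 3′ ends onto a reference transcript.

The promiscuous (endomotif-independent) endoribonuclease modality of
IRE1α fragments RNA at many positions. Its cut sites are read out by
ligating a known 3′ adapter to the fragments, cloning, and Sanger
sequencing: each read is fragment sequence followed by the adapter, so
the base immediately before the adapter is the fragment's last
(3′-terminal) nucleotide. This module

- trims the adapter by locating its seed prefix (mismatch-tolerant);
- maps each trimmed fragment to the reference by semiglobal alignment,
  recording the reference index of the fragment's last base (``end_pos``)
  and the cleaved dinucleotide ``(ref[end_pos], ref[end_pos + 1])`` —
  last sequenced base plus the next reference base;
- tallies per-position counts into a cleavage profile with hotspot calls;
- tests enrichment of G·C cleavage dinucleotides against the reference's
  background G·C-dinucleotide density with an exact binomial test.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats as sps

from riddkit.errors import DegenerateInputError, RiddkitError
from riddkit.seq_core import TranscriptRecord, normalize_sequence

#: 3′ adapter ligated to cleavage fragments before cloning.
DEFAULT_ADAPTER = "CAAGCAGAAGACGGCATACGAGATCGTGAT"


class MapStatus(enum.Enum):
    OK = "OK"
    NO_ADAPTER = "NO_ADAPTER"
    NO_MATCH = "NO_MATCH"
    AMBIGUOUS = "AMBIGUOUS"
    AT_3PRIME_TERMINUS = "AT_3PRIME_TERMINUS"
    EMPTY_FRAGMENT = "EMPTY_FRAGMENT"


@dataclass(frozen=True)
class AdapterConfig:
    """Adapter-trimming settings (seed prefix search, mismatch budget)."""

    adapter: str = DEFAULT_ADAPTER
    seed_len: int = 12
    seed_max_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.seed_len > len(self.adapter):
            raise ValueError("seed_len exceeds adapter length")


@dataclass(frozen=True)
class MappedEnd:
    """A read's mapped 3′ terminus on the reference."""

    read_id: str
    ref_id: str
    status: MapStatus
    end_pos: Optional[int] = None
    dinucleotide: Optional[Tuple[str, str]] = None

    @property
    def is_gc(self) -> bool:
        return self.dinucleotide == ("G", "C")


@dataclass
class CleavageProfile:
    """Per-position tally of mapped 3′ ends with hotspots."""

    ref_id: str
    counts: Dict[int, int]
    n_mapped: int
    n_gc: int
    hotspots: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def gc_fraction(self) -> float:
        if self.n_mapped == 0:
            return float("nan")
        return self.n_gc / self.n_mapped


@dataclass(frozen=True)
class EnrichmentResult:
    """Exact binomial test of G·C cleavage-site enrichment."""

    n_gc: int
    n_mapped: int
    background_p: float
    p_value: float


def trim_adapter(read: str, cfg: AdapterConfig = AdapterConfig()) -> Tuple[Optional[str], MapStatus]:
    """Split a read at the adapter; return (fragment, status).

    The leftmost window matching the adapter's first ``seed_len`` bases
    with at most ``seed_max_mismatch`` mismatches marks the adapter
    start; the fragment is the prefix before it. Returns
    ``(None, NO_ADAPTER)`` when no window qualifies and
    ``(None, EMPTY_FRAGMENT)`` when the adapter starts at position 0.
    """
    read = read.upper()
    seed = cfg.adapter.upper()[: cfg.seed_len]
    k = len(seed)
    for start in range(len(read) - k + 1):
        mm = sum(1 for a, b in zip(read[start : start + k], seed) if a != b)
        if mm <= cfg.seed_max_mismatch:
            if start == 0:
                return None, MapStatus.EMPTY_FRAGMENT
            return read[:start], MapStatus.OK
    return None, MapStatus.NO_ADAPTER


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free end gaps on the reference (target): semiglobal placement
    aligner.end_deletion_score = 0
    return aligner


def map_end(
    fragment: str,
    reference: TranscriptRecord,
    min_identity: float = 0.95,
    read_id: str = "",
) -> MappedEnd:
    """Locate a fragment's 3′-terminal base on the reference.

    Fast path: when the fragment occurs verbatim in the reference it is
    placed by exact substring search (multiple occurrences →
    ``AMBIGUOUS``). Otherwise semiglobal alignment (free end gaps on the
    reference; match +1, mismatch −1, gap −2) places it, accepted when
    the fraction of aligned identical bases is at least ``min_identity``;
    equal-best placements ending at distinct reference positions are
    ``AMBIGUOUS``. A fragment ending on the reference's final base has no
    subsequent nucleotide, hence ``AT_3PRIME_TERMINUS``.
    """
    if not fragment:
        return MappedEnd(read_id=read_id, ref_id=reference.id, status=MapStatus.EMPTY_FRAGMENT)
    frag = normalize_sequence(fragment)
    ref = reference.sequence

    first = ref.find(frag)
    if first != -1:
        if ref.find(frag, first + 1) != -1:
            return MappedEnd(read_id=read_id, ref_id=reference.id, status=MapStatus.AMBIGUOUS)
        end_pos = first + len(frag) - 1
    else:
        aligner = _make_aligner()
        alignments = aligner.align(ref, frag)
        try:
            best_score = alignments.score
        except (ValueError, IndexError):
            return MappedEnd(read_id=read_id, ref_id=reference.id, status=MapStatus.NO_MATCH)
        # identity of the first optimal alignment
        aln = alignments[0]
        ref_idx, frag_idx = aln.aligned
        matches = 0
        for (rs, re), (fs, fe) in zip(ref_idx, frag_idx):
            matches += sum(1 for a, b in zip(ref[rs:re], frag[fs:fe]) if a == b)
        if matches / len(frag) < min_identity:
            return MappedEnd(read_id=read_id, ref_id=reference.id, status=MapStatus.NO_MATCH)
        end_positions = set()
        for n, aln_i in enumerate(alignments):
            if n >= 16:  # more co-optimal layouts than any unique placement needs
                break
            if aln_i.score < best_score:
                break
            ref_blocks = aln_i.aligned[0]
            end_positions.add(ref_blocks[-1][1] - 1)
        if len(end_positions) > 1:
            return MappedEnd(read_id=read_id, ref_id=reference.id, status=MapStatus.AMBIGUOUS)
        end_pos = end_positions.pop()

    if end_pos + 1 >= len(ref):
        return MappedEnd(
            read_id=read_id, ref_id=reference.id,
            status=MapStatus.AT_3PRIME_TERMINUS, end_pos=end_pos,
        )
    return MappedEnd(
        read_id=read_id,
        ref_id=reference.id,
        status=MapStatus.OK,
        end_pos=end_pos,
        dinucleotide=(ref[end_pos], ref[end_pos + 1]),
    )


def tally_profile(
    ends: Sequence[MappedEnd],
    reference: TranscriptRecord,
    hotspot_min: Optional[int] = None,
    exclude_boundary: Optional[int] = None,
    exclude_window: int = 0,
) -> CleavageProfile:
    """Tally OK-status 3′ ends into a per-position cleavage profile.

    Hotspots are positions attracting at least ``hotspot_min`` reads
    (default ``max(3, ceil(0.05 · n_mapped))``), sorted by count
    descending. When ``exclude_boundary`` is given (e.g. a known
    endomotif scission site), ends within ``exclude_window`` positions of
    ``exclude_boundary − 1`` are omitted from the tally, so the profile
    describes cleavage outside the endomotif.
    """
    ref_ids = {e.ref_id for e in ends}
    if ref_ids and ref_ids != {reference.id}:
        raise RiddkitError(f"mapped ends from mixed references: {sorted(ref_ids)}")
    ok = [e for e in ends if e.status is MapStatus.OK]
    if exclude_boundary is not None:
        centre = exclude_boundary - 1  # end_pos of a read cut at that boundary
        ok = [e for e in ok if abs(e.end_pos - centre) > exclude_window]
    counts: Dict[int, int] = {}
    n_gc = 0
    for e in ok:
        counts[e.end_pos] = counts.get(e.end_pos, 0) + 1
        n_gc += int(e.is_gc)
    n_mapped = len(ok)
    if n_mapped == 0:
        warnings.warn("no OK-status ends; gc_fraction undefined", stacklevel=2)
        return CleavageProfile(ref_id=reference.id, counts={}, n_mapped=0, n_gc=0)
    if hotspot_min is None:
        hotspot_min = max(3, int(np.ceil(0.05 * n_mapped)))
    hotspots = sorted(
        ((pos, c) for pos, c in counts.items() if c >= hotspot_min),
        key=lambda pc: (-pc[1], pc[0]),
    )
    return CleavageProfile(
        ref_id=reference.id, counts=counts, n_mapped=n_mapped, n_gc=n_gc, hotspots=hotspots
    )


def gc_background(reference: TranscriptRecord) -> float:
    """Fraction of reference positions i with (ref[i], ref[i+1]) = (G, C)."""
    ref = reference.sequence
    n = len(ref) - 1
    if n <= 0:
        return 0.0
    return sum(1 for i in range(n) if ref[i : i + 2] == "GC") / n


def gc_enrichment(profile: CleavageProfile, reference: TranscriptRecord) -> EnrichmentResult:
    """Two-sided exact binomial test of G·C cleavage enrichment.

    Compares ``n_gc`` successes in ``n_mapped`` trials against the
    reference's background G·C-dinucleotide density.
    """
    if profile.n_mapped == 0:
        raise DegenerateInputError("no mapped ends; enrichment test undefined")
    p0 = gc_background(reference)
    if p0 == 0.0:
        if profile.n_gc > 0:
            warnings.warn("background GC density is zero but GC ends observed", stacklevel=2)
            pv = 0.0
        else:
            pv = 1.0
    else:
        pv = sps.binomtest(profile.n_gc, profile.n_mapped, p0, alternative="two-sided").pvalue
    return EnrichmentResult(
        n_gc=profile.n_gc, n_mapped=profile.n_mapped, background_p=p0, p_value=pv
    )


def map_reads(
    reads: Sequence[Tuple[str, str]],
    reference: TranscriptRecord,
    adapter_cfg: AdapterConfig = AdapterConfig(),
    min_identity: float = 0.95,
) -> List[MappedEnd]:
    """Trim and map a batch of (read_id, read_sequence) pairs."""
    out: List[MappedEnd] = []
    for read_id, seq in reads:
        fragment, status = trim_adapter(seq, adapter_cfg)
        if status is not MapStatus.OK:
            out.append(MappedEnd(read_id=read_id, ref_id=reference.id, status=status))
            continue
        out.append(map_end(fragment, reference, min_identity=min_identity, read_id=read_id))
    return out


def ends_table(ends: Sequence[MappedEnd]) -> pd.DataFrame:
    """Per-read mapping table (status, end position, cleaved dinucleotide)."""
    return pd.DataFrame(
        [
            {
                "read_id": e.read_id,
                "status": e.status.value,
                "end_pos": e.end_pos if e.end_pos is not None else pd.NA,
                "last_nt": e.dinucleotide[0] if e.dinucleotide else pd.NA,
                "next_nt": e.dinucleotide[1] if e.dinucleotide else pd.NA,
                "is_gc": e.is_gc,
            }
            for e in ends
        ],
        columns=["read_id", "status", "end_pos", "last_nt", "next_nt", "is_gc"],
    )


def profile_table(profile: CleavageProfile, reference: TranscriptRecord) -> pd.DataFrame:
    """Per-position profile table with the GC flag of each site."""
    ref = reference.sequence
    rows = [
        {
            "end_pos": pos,
            "count": c,
            "is_gc": ref[pos : pos + 2] == "GC",
        }
        for pos, c in sorted(profile.counts.items())
    ]
    return pd.DataFrame(rows, columns=["end_pos", "count", "is_gc"])
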