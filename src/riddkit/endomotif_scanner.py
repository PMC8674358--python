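"""Stem-loop endomotif scanner and RIDD/RIDDLE transcript classification.

IRE1α's sequence-specific endoribonuclease modality cleaves mRNAs at an
XBP1-like *endomotif*: a 7-nt consensus loop ``CNG|CAGN`` presented within
an energetically stable RNA hairpin, with scission of the backbone between
the G and C in the loop's third and fourth positions. The scanner

1. finds every 7-nt window conforming to the consensus at its five fixed
   positions (offsets ``0:C, 2:G, 3:C, 4:A, 5:G``), allowing at most
   ``max_mismatch`` substitutions there;
2. searches the flanking sequence for the best hairpin enclosing the loop,
   zipping a stem outward with a bounded budget of bulged (skipped) bases;
3. grades each hit as exact-canonical, variant-canonical (one consensus
   substitution), or sub-par (loop present but the stem fails the
   structural thresholds);
4. calls the transcript RIDD if any canonical hit exists, otherwise
   RIDDLE (with or without sub-par loops).

Stem stability is scored by a weighted pair count (G·C = 3, A·U = 2,
G·U = 1), a proxy for thermodynamic stability that keeps the search exact
and fast; the structural thresholds (minimum pairs, maximum unpaired bases,
maximum loop length, minimum stem score) are all configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from riddkit.errors import RangeError
from riddkit.seq_core import TranscriptRecord

HEPTAMER_LEN = 7
#: Fixed consensus positions of the CNG|CAGN loop heptamer.
CONSENSUS_FIXED: Dict[int, str] = {0: "C", 2: "G", 3: "C", 4: "A", 5: "G"}
#: Scission occurs between heptamer offsets 2 and 3 (third|fourth nt).
SCISSION_OFFSET = 3

#: Stem-stability weights per base pair.
PAIR_WEIGHTS: Dict[frozenset, int] = {
    frozenset("GC"): 3,
    frozenset("AU"): 2,
    frozenset("GU"): 1,
}


class Category(enum.Enum):
    """Grade of a single endomotif hit."""

    EXACT_CANONICAL = "EXACT_CANONICAL"
    VARIANT_CANONICAL = "VARIANT_CANONICAL"
    SUBPAR = "SUBPAR"


class TranscriptClass(enum.Enum):
    """Substrate class of a whole transcript."""

    RIDD = "RIDD"
    RIDDLE_SUBPAR = "RIDDLE_SUBPAR"
    RIDDLE_NONE = "RIDDLE_NONE"


@dataclass(frozen=True)
class ScannerConfig:
    """Tunable thresholds of the endomotif scanner.

    ``flank_window`` bounds how far the stem may extend on either side of
    the loop (the endomotif's structural context spans roughly 55–60
    flanking bases). ``min_pairs``, ``max_unpaired``, ``min_stem_score``
    and ``max_loop_len`` are the canonical-call thresholds; ``max_bulge_run``
    caps consecutive skipped bases on one strand of the stem.
    """

    max_mismatch: int = 1
    flank_window: int = 60
    max_loop_len: int = 9
    min_pairs: int = 5
    max_unpaired: int = 2
    min_stem_score: int = 12
    allow_gu_wobble: bool = True
    max_bulge_run: int = 2

    def __post_init__(self) -> None:
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if self.max_loop_len < HEPTAMER_LEN:
            raise ValueError("max_loop_len must be >= 7")
        if self.flank_window < self.max_loop_len:
            raise ValueError("flank_window must be >= max_loop_len")
        for name in ("min_pairs", "max_unpaired", "min_stem_score", "max_bulge_run"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LoopMatch:
    """A consensus-loop heptamer match on a transcript."""

    transcript_id: str
    start: int
    heptamer: str
    n_mismatch: int
    mismatch_positions: Tuple[int, ...]

    @property
    def cleavage_boundary(self) -> int:
        """Inter-nucleotide scission position (between heptamer offsets 2|3)."""
        return self.start + SCISSION_OFFSET


@dataclass(frozen=True)
class Hairpin:
    """The best stem enclosing a consensus loop.

    ``pairs`` holds (i, j) base-pair indices, outermost first, all nested
    and non-crossing; ``n_unpaired`` counts bulged bases inside the stem.
    """

    loop_start: int
    loop_end: int
    pairs: Tuple[Tuple[int, int], ...]
    n_unpaired: int
    stem_score: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def loop_len(self) -> int:
        return self.loop_end - self.loop_start


@dataclass(frozen=True)
class EndomotifHit:
    """A loop match plus its best hairpin and derived category."""

    match: LoopMatch
    hairpin: Optional[Hairpin]
    category: Category


@dataclass(frozen=True)
class TranscriptCall:
    """All hits on one transcript and the resulting RIDD/RIDDLE class."""

    transcript_id: str
    hits: Tuple[EndomotifHit, ...]
    transcript_class: TranscriptClass

    def n_in_category(self, category: Category) -> int:
        return sum(1 for h in self.hits if h.category is category)


def pair_weight(a: str, b: str, allow_gu_wobble: bool = True) -> int:
    """Stem weight of pairing bases ``a``/``b``; 0 if they cannot pair.

    N never pairs; G·U wobble counts only when enabled.
    """
    key = frozenset((a, b))
    w = PAIR_WEIGHTS.get(key, 0)
    if w == 1 and not allow_gu_wobble:
        return 0
    return w


def find_loop_matches(
    seq: str, config: ScannerConfig = ScannerConfig(), transcript_id: str = ""
) -> List[LoopMatch]:
    """Return all heptamer windows matching the CNG|CAGN consensus.

    Every 7-nt window is compared to the consensus at the five fixed
    offsets; windows with at most ``config.max_mismatch`` fixed-position
    mismatches are returned in ascending start order. ``N`` in the
    sequence never counts as a match at a fixed offset. A sequence
    shorter than 7 nt yields an empty list.
    """
    matches: List[LoopMatch] = []
    for start in range(len(seq) - HEPTAMER_LEN + 1):
        window = seq[start : start + HEPTAMER_LEN]
        mm = tuple(off for off, base in CONSENSUS_FIXED.items() if window[off] != base)
        if len(mm) <= config.max_mismatch:
            matches.append(
                LoopMatch(
                    transcript_id=transcript_id,
                    start=start,
                    heptamer=window,
                    n_mismatch=len(mm),
                    mismatch_positions=mm,
                )
            )
    return matches


# Move codes for stem-path reconstruction.
_STOP, _PAIR, _SKIP_L, _SKIP_R = 0, 1, 2, 3


def _best_stem(
    seq: str,
    i0: int,
    j0: int,
    lo: int,
    hi: int,
    config: ScannerConfig,
) -> Tuple[int, List[Tuple[int, int]], int]:
    """Maximum-score stem zipped outward from (i0, j0).

    Returns ``(stem_score, pairs, n_unpaired)`` of the optimum under the
    skip budgets, optimizing lexicographically by (score, n_pairs,
    -n_unpaired). ``lo``/``hi`` bound the search window: ``lo <= i`` and
    ``j < hi``. Trailing skips never appear in the optimum because a plain
    stop dominates them.
    """
    wobble = config.allow_gu_wobble
    max_run = config.max_bulge_run
    max_skips = config.max_unpaired

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, run_l: int, run_r: int, skips: int):
        # value: (score, n_pairs, -n_unpaired); move taken at this state
        best = (0, 0, 0, _STOP)
        if i >= lo and j < hi:
            w = pair_weight(seq[i], seq[j], wobble)
            if w > 0:
                s, p, nu, _ = rec(i - 1, j + 1, 0, 0, skips)
                cand = (s + w, p + 1, nu, _PAIR)
                if cand[:3] > best[:3]:
                    best = cand
            if skips < max_skips:
                if i >= lo and run_l < max_run:
                    s, p, nu, _ = rec(i - 1, j, run_l + 1, run_r, skips + 1)
                    cand = (s, p, nu - 1, _SKIP_L)
                    if cand[:3] > best[:3]:
                        best = cand
                if j < hi and run_r < max_run:
                    s, p, nu, _ = rec(i, j + 1, run_l, run_r + 1, skips + 1)
                    cand = (s, p, nu - 1, _SKIP_R)
                    if cand[:3] > best[:3]:
                        best = cand
        return best

    # Reconstruct the optimal path.
    pairs: List[Tuple[int, int]] = []
    i, j, run_l, run_r, skips = i0, j0, 0, 0, 0
    score, _, neg_unpaired, _ = rec(i, j, run_l, run_r, skips)
    while True:
        _, _, _, move = rec(i, j, run_l, run_r, skips)
        if move == _STOP:
            break
        if move == _PAIR:
            pairs.append((i, j))
            i, j, run_l, run_r = i - 1, j + 1, 0, 0
        elif move == _SKIP_L:
            i, run_l, skips = i - 1, run_l + 1, skips + 1
        else:
            j, run_r, skips = j + 1, run_r + 1, skips + 1
    rec.cache_clear()
    return score, pairs, -neg_unpaired


def enumerate_hairpin(
    seq: str, match: LoopMatch, config: ScannerConfig = ScannerConfig()
) -> Optional[Hairpin]:
    """Best hairpin enclosing ``match``'s heptamer, or ``None``.

    Candidate loops are all intervals ``[ls, le)`` containing the heptamer
    with length at most ``max_loop_len``; for each, a stem is zipped
    outward from ``(ls - 1, le)``, pairing bases or skipping one base per
    step (a bulge) within the bulge-run and total-unpaired budgets, never
    extending beyond ``flank_window`` bases from the heptamer. The
    maximum-score hairpin wins; ties break toward more pairs, fewer
    unpaired bases, a shorter loop, then the smaller loop start.
    """
    hept_start = match.start
    hept_end = match.start + HEPTAMER_LEN
    lo = max(0, hept_start - config.flank_window)
    hi = min(len(seq), hept_end + config.flank_window)

    best: Optional[Tuple[Tuple[int, int, int, int, int], Hairpin]] = None
    for loop_len in range(HEPTAMER_LEN, config.max_loop_len + 1):
        for ls in range(hept_end - loop_len, hept_start + 1):
            le = ls + loop_len
            if ls < 1 or le >= len(seq):
                continue
            score, pairs, n_unpaired = _best_stem(seq, ls - 1, le, lo, hi, config)
            if not pairs:
                continue
            hp = Hairpin(
                loop_start=ls,
                loop_end=le,
                pairs=tuple(pairs),
                n_unpaired=n_unpaired,
                stem_score=score,
            )
            key = (score, len(pairs), -n_unpaired, -loop_len, -ls)
            if best is None or key > best[0]:
                best = (key, hp)
    return best[1] if best else None


def classify_hit(
    match: LoopMatch,
    hairpin: Optional[Hairpin],
    config: ScannerConfig = ScannerConfig(),
) -> EndomotifHit:
    """Grade a loop match by its hairpin against the canonical thresholds."""
    canonical = (
        hairpin is not None
        and hairpin.n_pairs >= config.min_pairs
        and hairpin.n_unpaired <= config.max_unpaired
        and hairpin.stem_score >= config.min_stem_score
        and hairpin.loop_len <= config.max_loop_len
    )
    if canonical:
        category = Category.EXACT_CANONICAL if match.n_mismatch == 0 else Category.VARIANT_CANONICAL
    else:
        category = Category.SUBPAR
    return EndomotifHit(match=match, hairpin=hairpin, category=category)


def scan_transcript(
    record: TranscriptRecord, config: ScannerConfig = ScannerConfig()
) -> TranscriptCall:
    """Scan one transcript and call its RIDD/RIDDLE class.

    RIDD requires at least one exact- or variant-canonical hit; a
    transcript with only sub-par loop matches is RIDDLE_SUBPAR; one with
    no loop match at all is RIDDLE_NONE.
    """
    hits = tuple(
        classify_hit(m, enumerate_hairpin(record.sequence, m, config), config)
        for m in find_loop_matches(record.sequence, config, transcript_id=record.id)
    )
    if any(h.category in (Category.EXACT_CANONICAL, Category.VARIANT_CANONICAL) for h in hits):
        cls = TranscriptClass.RIDD
    elif hits:
        cls = TranscriptClass.RIDDLE_SUBPAR
    else:
        cls = TranscriptClass.RIDDLE_NONE
    return TranscriptCall(transcript_id=record.id, hits=hits, transcript_class=cls)


def predict_fragments(record: TranscriptRecord, boundaries: Sequence[int]) -> List[int]:
    """Fragment lengths produced by cutting at the given boundaries.

    ``boundaries`` must be strictly increasing internal cleavage positions
    (``0 < b < len``). Cutting at k boundaries yields k+1 fragment lengths
    summing to the transcript length; with two boundaries the middle
    fragment is the excised-intron length.
    """
    n = len(record)
    prev = -1
    for b in boundaries:
        if b <= 0 or b >= n:
            raise RangeError(f"cleavage boundary {b} outside (0, {n})")
        if b <= prev:
            raise RangeError("cleavage boundaries must be strictly increasing")
        prev = b
    cuts = [0, *boundaries, n]
    return [cuts[k + 1] - cuts[k] for k in range(len(cuts) - 1)]


# ---------------------------------------------------------------------------
# Tabular output

def hits_table(calls: Sequence[TranscriptCall]) -> pd.DataFrame:
    """Flatten hits of many transcript calls into a tidy table."""
    rows = []
    for call in calls:
        for h in call.hits:
            hp = h.hairpin
            rows.append(
                {
                    "transcript_id": call.transcript_id,
                    "start": h.match.start,
                    "heptamer": h.match.heptamer,
                    "n_mismatch": h.match.n_mismatch,
                    "category": h.category.value,
                    "loop_start": hp.loop_start if hp else pd.NA,
                    "loop_end": hp.loop_end if hp else pd.NA,
                    "n_pairs": hp.n_pairs if hp else 0,
                    "n_unpaired": hp.n_unpaired if hp else 0,
                    "stem_score": hp.stem_score if hp else 0,
                    "cleavage_boundary": h.match.cleavage_boundary,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "start", "heptamer", "n_mismatch", "category",
            "loop_start", "loop_end", "n_pairs", "n_unpaired", "stem_score",
            "cleavage_boundary",
        ],
    )


def calls_table(calls: Sequence[TranscriptCall]) -> pd.DataFrame:
    """Per-transcript class summary table."""
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "transcript_class": c.transcript_class.value,
                "n_exact": c.n_in_category(Category.EXACT_CANONICAL),
                "n_variant": c.n_in_category(Category.VARIANT_CANONICAL),
                "n_subpar": c.n_in_category(Category.SUBPAR),
            }
            for c in calls
        ],
        columns=["transcript_id", "transcript_class", "n_exact", "n_variant", "n_subpar"],
    )


def write_cleavage_bed(calls: Sequence[TranscriptCall], path) -> None:
    """Write canonical-hit cleavage boundaries as single-base BED features.

    Coordinates are 0-based half-open on the transcript (transcript id as
    the chrom column); the feature covers the base immediately 3′ of the
    scission.
    """
    with open(path, "w") as fh:
        for call in calls:
            for h in call.hits:
                b = h.match.cleavage_boundary
                fh.write(
                    f"{call.transcript_id}\t{b}\t{b + 1}\t{h.category.value}\t"
                    f"{h.hairpin.stem_score if h.hairpin else 0}\t+\n"
                )
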