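"""Seeded generators of synthetic inputs for every analysis module.

Each generator is a pure function of its seed and spec and carries its
own ground truth, so sensitivity/specificity of the downstream modules
can be computed without re-deriving labels:

- :func:`make_transcript` — random-background transcripts with implanted
  stem-loop endomotifs of chosen grade (exact/variant consensus loop on a
  stable stem, sub-par loop without a stem, or no motif at all), with
  flanks rejection-sampled so no unintended canonical hit appears;
- :func:`make_count_dataset` — negative-binomial RNAseq + GROseq count
  tables over the WT/KO × DMSO/Tg design with implanted decay,
  transcriptional, and IRE1-independent effects;
- :func:`make_fragment_reads` — adapter-ligated cleavage-fragment reads
  from chosen cut sites on a reference transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from riddkit.cleavage_map import DEFAULT_ADAPTER
from riddkit.endomotif_scanner import (
    CONSENSUS_FIXED,
    HEPTAMER_LEN,
    Category,
    ScannerConfig,
    TranscriptClass,
    find_loop_matches,
    scan_transcript,
)
from riddkit.errors import GenerationError
from riddkit.seq_core import TranscriptRecord

RNA_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Flank length of pairing-inert context placed around sub-par loops.
_INERT_FLANK = 15


@dataclass(frozen=True)
class ImplantSpec:
    """One endomotif implant: grade, stem geometry, and placement.

    ``category`` NONE contributes no sequence — a transcript whose
    implants are all NONE is rejection-sampled to contain no consensus
    loop match at all.
    """

    category: str = "EXACT"          # EXACT | VARIANT | SUBPAR | NONE
    stem_len: int = 7
    loop_len: int = 7
    position: Optional[int] = None   # transcript offset of the implant block
    gc_stem_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.category not in ("EXACT", "VARIANT", "SUBPAR", "NONE"):
            raise ValueError(f"unknown implant category {self.category!r}")
        if not (HEPTAMER_LEN <= self.loop_len):
            raise ValueError("loop_len must be >= 7")

    @property
    def n_mismatch(self) -> int:
        return 1 if self.category == "VARIANT" else 0

    @property
    def block_len(self) -> int:
        if self.category in ("EXACT", "VARIANT"):
            return 2 * self.stem_len + self.loop_len
        if self.category == "SUBPAR":
            return 2 * _INERT_FLANK + self.loop_len
        return 0


@dataclass(frozen=True)
class ImplantTruth:
    """Ground truth for one placed implant."""

    category: str
    position: int
    heptamer_start: int
    cleavage_boundary: int


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = RNA_BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _consensus_heptamer(rng: np.random.Generator, n_mismatch: int) -> str:
    bases = []
    for off in range(HEPTAMER_LEN):
        if off in CONSENSUS_FIXED:
            bases.append(CONSENSUS_FIXED[off])
        else:
            bases.append(RNA_BASES[rng.integers(0, 4)])
    if n_mismatch:
        off = list(CONSENSUS_FIXED)[rng.integers(0, len(CONSENSUS_FIXED))]
        alternatives = [b for b in RNA_BASES if b != CONSENSUS_FIXED[off]]
        bases[off] = alternatives[rng.integers(0, 3)]
    return "".join(bases)


def _stem_arm(rng: np.random.Generator, spec: ImplantSpec) -> str:
    n_gc = int(round(spec.gc_stem_fraction * spec.stem_len))
    arm = list(
        _random_seq(rng, n_gc, "GC") + _random_seq(rng, spec.stem_len - n_gc, "AU")
    )
    rng.shuffle(arm)  # type: ignore[arg-type]
    return "".join(arm)


def _implant_block(rng: np.random.Generator, spec: ImplantSpec) -> Tuple[str, int]:
    """Return (block sequence, heptamer offset within the block)."""
    heptamer = _consensus_heptamer(rng, spec.n_mismatch)
    loop = heptamer + _random_seq(rng, spec.loop_len - HEPTAMER_LEN)
    if spec.category in ("EXACT", "VARIANT"):
        arm = _stem_arm(rng, spec)
        return arm + loop + _revcomp(arm), spec.stem_len
    # SUBPAR: loop in pairing-inert (A/C-only) context, so no stem can zip
    return (
        _random_seq(rng, _INERT_FLANK, "AC") + loop + _random_seq(rng, _INERT_FLANK, "AC")
    ), _INERT_FLANK


def make_transcript(
    rng_seed: int,
    length: int = 300,
    implants: Sequence[ImplantSpec] = (ImplantSpec(),),
    transcript_id: str = "synthetic",
    config: ScannerConfig = ScannerConfig(),
    max_attempts: int = 1000,
) -> Tuple[TranscriptRecord, List[ImplantTruth]]:
    """A random transcript carrying the requested endomotif implants.

    Implant blocks (stem arm + consensus loop + complementary arm, or an
    unpairable sub-par loop) are placed at the requested or random
    non-overlapping positions in a uniform-random background. The whole
    transcript is rejection-sampled until the scanner under ``config``
    reproduces exactly the intended canonical hits (no accidental
    canonical hit elsewhere, sub-par implants graded sub-par, all-NONE
    transcripts free of any loop match). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    real = [s for s in implants if s.category != "NONE"]
    motif_free = any(s.category == "NONE" for s in implants) and not real
    total_block = sum(s.block_len for s in real)
    if total_block > length:
        raise GenerationError("implants do not fit within the transcript length")

    for _ in range(max_attempts):
        blocks: List[Tuple[int, str, ImplantSpec, int]] = []  # (pos, seq, spec, hept_off)
        taken: List[Tuple[int, int]] = []
        ok_layout = True
        for spec in real:
            block, hept_off = _implant_block(rng, spec)
            if spec.position is not None:
                pos = spec.position
            else:
                pos = int(rng.integers(0, length - len(block) + 1))
            if pos < 0 or pos + len(block) > length or any(
                pos < e and s < pos + len(block) for s, e in taken
            ):
                ok_layout = False
                break
            taken.append((pos, pos + len(block)))
            blocks.append((pos, block, spec, hept_off))
        if not ok_layout:
            continue

        seq = list(_random_seq(rng, length))
        for pos, block, _, _ in blocks:
            seq[pos : pos + len(block)] = block
        sequence = "".join(seq)

        truths = [
            ImplantTruth(
                category=spec.category,
                position=pos,
                heptamer_start=pos + hept_off,
                cleavage_boundary=pos + hept_off + 3,
            )
            for pos, _, spec, hept_off in blocks
        ]

        if not real:
            if not motif_free or not find_loop_matches(sequence, config):
                return TranscriptRecord(id=transcript_id, sequence=sequence), []
            continue

        call = scan_transcript(TranscriptRecord(id=transcript_id, sequence=sequence), config)
        canonical = {
            h.match.start: h.category
            for h in call.hits
            if h.category in (Category.EXACT_CANONICAL, Category.VARIANT_CANONICAL)
        }
        subpar_starts = {h.match.start for h in call.hits if h.category is Category.SUBPAR}
        expected_canonical = {
            t.heptamer_start: Category.EXACT_CANONICAL if t.category == "EXACT"
            else Category.VARIANT_CANONICAL
            for t in truths
            if t.category in ("EXACT", "VARIANT")
        }
        if canonical != expected_canonical:
            continue
        if any(
            t.heptamer_start not in subpar_starts for t in truths if t.category == "SUBPAR"
        ):
            continue
        return TranscriptRecord(id=transcript_id, sequence=sequence), truths

    raise GenerationError(f"rejection sampling failed after {max_attempts} attempts")


@dataclass(frozen=True)
class CountSimSpec:
    """Design of the synthetic dual-assay count experiment.

    Defaults mirror the study layout: WT and IRE1α-KO cells, vehicle
    (DMSO) vs Tg 8 h, three biological replicates, assayed by both
    RNAseq and GROseq. Implanted decay genes lose abundance only in
    (WT, Tg, RNAseq); transcriptional genes lose it in both assays (WT
    only); IRE1-independent genes lose steady-state abundance in WT and
    KO alike.
    """

    n_genes: int = 2000
    n_implanted_ridd: int = 12
    n_transcriptional: int = 10
    n_ire1_independent: int = 10
    effect_log2fc: float = -1.0
    nb_dispersion: float = 0.1
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_implanted_ridd + self.n_transcriptional + self.n_ire1_independent > self.n_genes:
            raise ValueError("implanted gene classes exceed n_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def make_count_dataset(spec: CountSimSpec):
    """Simulate the paired RNAseq/GROseq count matrices with truth labels.

    Returns ``(rna, gro, truth)`` where ``truth`` is a DataFrame with
    columns ``gene`` and ``cls`` ∈ {ridd, transcriptional,
    ire1_independent, null}.
    """
    from riddkit.decay_filter import Assay, CountMatrix  # local import: avoid cycle

    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    base = 2.0 ** rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)

    idx = rng.permutation(spec.n_genes)
    n1, n2, n3 = spec.n_implanted_ridd, spec.n_transcriptional, spec.n_ire1_independent
    cls = np.array(["null"] * spec.n_genes, dtype=object)
    cls[idx[:n1]] = "ridd"
    cls[idx[n1 : n1 + n2]] = "transcriptional"
    cls[idx[n1 + n2 : n1 + n2 + n3]] = "ire1_independent"
    truth = pd.DataFrame({"gene": genes, "cls": cls})

    effect = 2.0 ** spec.effect_log2fc

    def stratum_mu(assay: str, genotype: str, treatment: str) -> np.ndarray:
        mu = base.copy()
        if treatment != "TG8H":
            return mu
        hit = np.zeros(spec.n_genes, dtype=bool)
        if assay == "RNASEQ" and genotype == "WT":
            hit |= cls == "ridd"
        if genotype == "WT":
            hit |= cls == "transcriptional"       # both assays: true transcription change
        if assay == "RNASEQ":
            hit |= cls == "ire1_independent"      # WT and KO alike
        mu[hit] *= effect
        return mu

    matrices = {}
    for assay, tag in (("RNASEQ", "rna"), ("GROSEQ", "gro")):
        cols, meta_rows = {}, []
        for genotype in ("WT", "KO"):
            for treatment in ("DMSO", "TG8H"):
                mu = stratum_mu(assay, genotype, treatment)
                for rep in range(1, spec.replicates + 1):
                    name = f"{tag}_{genotype.lower()}_{treatment.lower()}_{rep}"
                    cols[name] = _nb_sample(rng, mu, spec.nb_dispersion)
                    meta_rows.append(
                        {"sample": name, "genotype": genotype, "treatment": treatment,
                         "replicate": rep}
                    )
        counts = pd.DataFrame(cols, index=genes)
        meta = pd.DataFrame(meta_rows).set_index("sample")
        matrices[assay] = CountMatrix(counts=counts, metadata=meta, assay=Assay[assay])

    return matrices["RNASEQ"], matrices["GROSEQ"], truth


def make_fragment_reads(
    rng_seed: int,
    reference: TranscriptRecord,
    cut_sites: Sequence[Tuple[int, float]],
    n_reads: Optional[int] = None,
    error_rate: float = 0.0,
    adapter: str = DEFAULT_ADAPTER,
) -> Tuple[List[Tuple[str, str]], Dict[str, int]]:
    """Simulate adapter-ligated 5′ cleavage fragments as DNA reads.

    Each read is ``reference[0:boundary]`` (U→T) followed by the
    adapter, with substitution errors applied to the fragment portion at
    ``error_rate``. Boundaries are drawn from ``cut_sites`` weights when
    ``n_reads`` is given; with ``n_reads=None`` the weights are taken as
    exact integer read counts per site. Returns the reads and a truth map
    read id → cleavage boundary.
    """
    rng = np.random.default_rng(rng_seed)
    n = len(reference)
    for b, w in cut_sites:
        if not (0 < b < n):
            raise GenerationError(f"cut boundary {b} outside (0, {n})")
        if w < 0:
            raise GenerationError("cut-site weights must be >= 0")
    if not any(w > 0 for _, w in cut_sites):
        raise GenerationError("cut-site weights must not all be zero")

    if n_reads is None:
        boundaries = [b for b, w in cut_sites for _ in range(int(round(w)))]
    else:
        sites = np.array([b for b, _ in cut_sites])
        w = np.array([w for _, w in cut_sites], dtype=float)
        boundaries = list(rng.choice(sites, size=n_reads, p=w / w.sum()))

    dna_ref = reference.sequence.replace("U", "T")
    reads: List[Tuple[str, str]] = []
    truth: Dict[str, int] = {}
    for k, b in enumerate(boundaries):
        frag = list(dna_ref[: int(b)])
        if error_rate > 0:
            for i in range(len(frag)):
                if rng.random() < error_rate:
                    frag[i] = "ACGT"[rng.integers(0, 4)]
        read_id = f"read{k:05d}"
        reads.append((read_id, "".join(frag) + adapter.upper()))
        truth[read_id] = int(b)
    return reads, truth


def write_reads_fasta(reads: Sequence[Tuple[str, str]], path) -> None:
    """Write (id, sequence) read pairs as plain FASTA."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f">{read_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
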