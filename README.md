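# riddkit

Toolkit for analyzing the two endoribonuclease modalities of IRE1α, the
ER-stress sensor whose RNase both splices XBP1u mRNA and degrades cellular
mRNAs. The first modality — regulated IRE1-dependent decay (**RIDD**) —
cleaves transcripts at an XBP1-like *stem-loop endomotif*: a 7-nt consensus
loop `CNG|CAGN` presented on a stable RNA hairpin, with scission of the
backbone between the G and C in the loop's third and fourth positions. The
second — **RIDDLE** ("RIDD lacking endomotif") — is a promiscuous,
endomotif-independent activity of IRE1α phospho-oligomers that favors G·C
dinucleotide sites.

riddkit is for researchers who need to (i) classify transcripts as
candidate RIDD vs RIDDLE substrates from sequence, (ii) call
IRE1α-dependent decay candidates from paired steady-state (RNAseq) and
nascent (GROseq) count data, (iii) map endonucleolytic cleavage sites from
adapter-ligated fragment reads, and (iv) score RIDD/RIDDLE gene signatures
in expression cohorts.

## What it computes

**Endomotif scanner** (`riddkit.endomotif_scanner`). Every 7-nt window is
tested against the consensus `C N G | C A G N` at its five fixed positions
(≤1 substitution allowed). For each loop match the best enclosing hairpin
is found by zipping a stem outward through the flanking sequence (≤60 nt
each side), pairing bases or skipping single bulged bases within a bounded
budget. Stem stability is the weighted pair count

    S = 3·n(G·C) + 2·n(A·U) + 1·n(G·U)

A hit is *canonical* when the hairpin reaches ≥5 pairs, ≤2 unpaired bases,
S ≥ 12, and loop ≤ 9 nt — exact or variant by the number of consensus
substitutions — else *sub-par*. A transcript with any canonical hit is
RIDD; with only sub-par loops, RIDDLE (sub-par); with none, RIDDLE (no
motif). Cleavage boundaries feed `predict_fragments`, which partitions a
transcript into the fragment lengths a digestion gel would show.

**Decay filter** (`riddkit.decay_filter`). Counts from a WT / IRE1α-KO ×
DMSO / Tg-8h design in both assays are CPM-filtered (CPM > 1 in ≥3
samples), TMM-normalized, and summarized per gene as log2 fold changes
log2FC = mean log-CPM(Tg) − mean log-CPM(DMSO) per assay × genotype, with
a moderated t-test (empirical-Bayes variance shrinkage) and
Benjamini–Hochberg FDR on the WT RNAseq contrast. Decay candidates must
pass: p and FDR ≤ 0.05; log2FC(KO) − log2FC(WT) ≥ 0.5 (IRE1α dependence);
average log-CPM ≥ 1; log2FC(WTrna) − log2FC(WTgro) ≤ −0.3 (steady state
falls below nascent, i.e. decay not transcription); and a ≥1.4-fold
steady-state decrease.

**Cleavage mapper** (`riddkit.cleavage_map`). Fragment reads are split at
the ligated 3′ adapter (`caagcagaagacggcatacgagatCGTGAT`, seed-prefix
search, 1 mismatch), placed on the reference by semiglobal alignment, and
tallied by the reference index of each fragment's last base. The cleaved
dinucleotide is (last sequenced base, next reference base); G·C-site
enrichment is tested against the reference's background G·C density with
an exact binomial test, and recurrent positions are called hotspots.

**Signature scores** (`riddkit.signature_score`). Per-sample mean of
per-gene Z-scores (n−1 sd, within stratum) over the built-in RIDD
(BLOC1S1, PIGQ, TGOLN2, DGAT2, WT1, GBA, CD59, BMP4) or RIDDLE (BCAM,
CCDC69, MFAP2, SNN, SIX2, AIM2, OAS2, CFAP45, TNFAIP8L1) sets, with a
HIGH/LOW split at the within-stratum median.

**Synthetic fixtures** (`riddkit.synthetic_fixtures`). Seeded generators
for transcripts with implanted endomotifs, negative-binomial dual-assay
count tables with implanted decay/transcriptional effects, and
adapter-ligated fragment reads — each carrying ground-truth labels.

## Worked example

Generate four transcripts with one implanted exact endomotif each, then
scan them:

```sh
$ riddkit simulate transcripts --seed 11 --n 4 --category EXACT \
    --out-fasta demo.fa --out-truth demo_truth.tsv
$ riddkit scan --fasta demo.fa --out-hits hits.tsv --out-calls calls.tsv
scanned 4 transcripts: 4 RIDD, 0 RIDDLE
$ head -2 hits.tsv
transcript_id  start  heptamer  n_mismatch  category         loop_start  loop_end  n_pairs  n_unpaired  stem_score  cleavage_boundary
tx0000         100    CCGCAGC   0           EXACT_CANONICAL  100         107       10       2           26          103
```

The implanted loop `CCGCAGC` at position 100 sits on a 10-pair hairpin of
stem score 26, so the hit is exact-canonical and the transcript is called
RIDD; scission is predicted at boundary 103, between the loop's G and C.
Cutting a transcript at two such boundaries returns the fragment sizes a
digestion would produce:

```sh
$ riddkit fragments --fasta demo.fa --boundaries "110,136"
tx0000	110,26,164
```

i.e. a 5′ fragment, a 26-nt excised intron, and a 3′ fragment. The other
subcommands follow the same pattern: `riddkit filter` (decay candidates
from count TSVs), `riddkit cleavage` (fragment 3′-end mapping and GC
enrichment), `riddkit score` (signature scores), and `riddkit simulate
counts|reads`.

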