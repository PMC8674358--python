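# Methods notes

## Endomotif model

The scanner models the substrate of IRE1α's sequence-specific RNase
modality as a stem-loop whose loop carries the 7-nt consensus
`C N G | C A G N`. Only the five fixed offsets (0:C, 2:G, 3:C, 4:A, 5:G)
are constrained; offsets 1 and 6 are free. Scission is fixed between loop
offsets 2 and 3 (the third and fourth nucleotides) regardless of where a
variant substitution falls, because the scissile bond is set by the
enzyme's active-site geometry, not by the mismatch. `N` in a sequence
never satisfies a fixed position and never pairs in a stem: degenerate
bases cannot support either recognition or stability.

### Hairpin search

For each loop match, candidate loops are all intervals containing the
heptamer with length 7–`max_loop_len`. From each candidate's closing
positions a stem is zipped outward, at each step either pairing the next
upstream/downstream bases or skipping a single base on one side (a
bulge). The search is exact: a memoized dynamic program over
(5′ index, 3′ index, consecutive-skip counters, total skips) maximizes
the stem score lexicographically by (score, pairs, −unpaired). Trailing
skips never appear in an optimum because stopping dominates them. Ties
across candidate loops break toward more pairs, fewer unpaired bases, a
shorter loop, then the 5′-most loop start — fixed tie-breaks make scans
deterministic and order-independent. The test suite checks the search
against an independent brute-force path enumeration on small windows.

Stem stability is a weighted pair count (G·C = 3, A·U = 2, G·U = 1), a
monotone proxy for thermodynamic stability chosen over a nearest-neighbor
energy model to keep the search exact, fast, and dependency-free; a
thermodynamic backend could be substituted behind the same `Hairpin`
contract without changing any interface.

### Thresholds (defaults, all CLI-exposed)

| parameter        | default | meaning                                            |
|------------------|---------|----------------------------------------------------|
| `max_mismatch`   | 1       | substitutions tolerated at fixed loop positions    |
| `flank_window`   | 60 nt   | how far the stem may reach past the loop           |
| `max_loop_len`   | 9 nt    | longest loop accepted for a canonical call         |
| `min_pairs`      | 5       | minimum stem pairs for a canonical call            |
| `max_unpaired`   | 2       | bulged bases tolerated inside the stem             |
| `min_stem_score` | 12      | minimum weighted pair score                        |
| `max_bulge_run`  | 2 nt    | longest consecutive bulge on one strand            |
| `allow_gu_wobble`| true    | count G·U pairs (weight 1)                         |

The flanking window reflects the ~55–60 bases of structural context the
endomotif needs; 60 is used as a single configurable window rather than a
searched range. The structural thresholds are calibration defaults — the
weakest settings under which a designed 5-pair, no-bulge hairpin of mixed
G·C/A·U content is accepted while unstructured consensus loops are
rejected; they are deliberately conservative and configurable rather than
asserted as biologically sharp.

A transcript is RIDD with ≥1 canonical (exact or variant) hit,
RIDDLE_SUBPAR with only sub-par loop matches, RIDDLE_NONE with no loop
match. All overlapping matches are reported; the class depends only on
the best category present.

## Decay filter

Counts are modeled per sample from a WT / IRE1α-KO × DMSO / Tg-8h design
assayed by RNAseq (steady state) and GROseq (nascent transcription), ≥2
replicates per cell. The pipeline:

1. **Expression filter** — keep genes with CPM > 1 in ≥3 samples,
   computed on raw library sizes across the concatenated assays.
2. **TMM scaling** — trimmed mean of M-values with 30%/5% log-ratio and
   abundance trims and delta-method precision weights. M-values are
   computed on raw counts against the reference sample (the one whose
   75th-percentile count fraction is closest to the across-sample mean),
   so each factor captures the sample's relative abundance — an
   *effective library size* factor, normalized to multiply to 1. Log-CPM
   therefore uses the factor scaled to the geometric-mean library size.
   Degenerate inputs (single gene, all-zero sample) are errors, not NaNs.
3. **Contrasts** — per gene, log2FC = mean log-CPM(Tg8h) − mean
   log-CPM(DMSO) within each assay × genotype stratum, with a
   prior count (0.5, library-size-scaled) so zero counts stay finite.
4. **Moderated test** — the WT RNAseq contrast gets a two-sided t-test
   with empirical-Bayes variance shrinkage: a scaled inverse-chi-square
   prior is fitted to the marginal distribution of the pooled per-gene
   variances by method of moments, and posterior-mean variances are used
   with residual + prior degrees of freedom. With `moderation=false` a
   plain pooled t is used; zero-variance genes report p = 1 with a
   `degenerate` flag (variances below 1e-20 are clamped to zero — they
   arise from rounding, not biology). This is intentionally simpler than
   observation-weighted linear-model frameworks; precomputed statistics
   can be supplied as TSV to bypass it entirely, since the package's
   contribution is the candidate filter, not the DE engine.
5. **Filter chain** — survivors pass *all* enabled criteria; per-criterion
   flags are always emitted so the chain is auditable and order-free:
   significance (p ≤ α and FDR ≤ α, α = 0.05); IRE1α dependence
   (log2FC(KO) − log2FC(WT) ≥ 0.5); expression (average log-CPM ≥ 1);
   decay vs transcription (log2FC(WTrna) − log2FC(WTgro) ≤ −0.3); and an
   optional fold criterion (log2FC(WTrna) ≤ −log2 1.4).

Two readings of the published text are kept available. The significance
criterion defaults to the stricter both-≤-α rule (equivalent to
FDR ≤ α, since BH guarantees q ≥ p); the literal removal sentence would
keep any gene with p ≤ α alone. The decay-vs-transcription criterion
defaults to the biologically meaningful direction (steady state falls at
least 0.3 log2 below nascent); `literal_sign_mode` flips it to the ≥
reading of the removal sentence verbatim. Neither choice is guessed
silently — both are flags.

### Statistical limits at the reference simulation settings

The reference simulation (2,000 genes, 3 replicates, NB dispersion 0.1,
effect −1.0 log2) is deliberately noisy. At dispersion 0.1 the log2-CPM
variance per observation is ≈ 0.1/ln²2 ≈ 0.21, so a true −1.0 effect
yields an expected |t| ≈ 1/√(2·0.21/3) ≈ 2.6 (p ≈ 0.01) — while BH at
α = 0.05 with ~32 affected genes among 2,000 requires p ≲ 8×10⁻⁴. Even an
oracle z-test with known variance cannot pass the FDR criterion for an
average implant, so the chain's sensitivity at these settings is near
zero and its false-positive count near zero; the acceptance script
reports both honestly. This is a property of the chosen noise regime, not
of the chain: at dispersion ≤ 0.01 (typical for cell-line replicates) the
implanted genes separate cleanly, which is what the low-dispersion tests
exercise. The corresponding full-recovery test is left failing rather
than weakening the conditions or the criterion.

## Cleavage mapping

Reads are fragment + ligated 3′ adapter. The adapter is located by its
first 12 bases with ≤1 mismatch (leftmost hit); Sanger-scale reads are
long and accurate enough that full-adapter alignment adds nothing. The
fragment is placed by semiglobal alignment — global over the fragment,
free end gaps on the reference, scores +1/−1/−2, acceptance at ≥95%
identity — with an exact-substring fast path. `end_pos` is the reference
index of the fragment's last base; the cleaved dinucleotide is
(ref[end_pos], ref[end_pos+1]), i.e. last sequenced base plus the next
reference base, so "G·C site" means the fragment ends on a G directly
followed by C in the reference. Co-optimal placements with distinct end
positions are AMBIGUOUS (short prefixes of repetitive references are
flagged, never guessed); a fragment reaching the reference's final base
has no next nucleotide and is AT_3PRIME_TERMINUS.

Hotspots are positions with ≥ max(3, ⌈5% of mapped reads⌉) ends — a
pragmatic default, not an asserted constant. GC enrichment is a two-sided
exact binomial test of the mapped G·C-end count against the reference's
background G·C-dinucleotide density; an optional exclusion window drops
ends at a supplied endomotif boundary so the promiscuous activity can be
quantified separately from consensus-site cleavage. Reads are assumed
sense-strand (primer-anchored clones); reverse-complement search is out
of scope.

## Signature scores

Genes are Z-scored within each stratum (disease type) with the sample
(n−1) standard deviation; zero-variance genes become all-zero rows with a
warning rather than NaNs. A sample's score is the mean Z over the unique
set members present (an error below 50% coverage); the HIGH/LOW split is
at the within-stratum median with ties assigned LOW. Z-scoring within
stratum (rather than globally before a per-stratum split) is the default
because the downstream split is per stratum; a global mode is available.
Survival modeling on the resulting groups is intentionally out of scope —
the emitted labels are what such a model would consume.

## Synthetic data: what it does and does not show

`make_transcript` embeds designed hairpins (complementary arms around a
consensus loop; sub-par loops get pairing-inert A/C flanks) in uniform
random background, rejection-sampling until the scanner's verdict on the
whole transcript matches the construction — so truth labels are exact by
construction, and implant-recovery results measure the scanner's
arithmetic, not biological prevalence. `make_count_dataset` draws
NB(mean, dispersion) counts (variance μ + φμ²) with class-specific
effects: decay genes fall only in (WT, Tg, RNAseq); transcriptional genes
fall in both assays (WT only); IRE1-independent genes fall in WT and KO
RNAseq. `make_fragment_reads` concatenates reference prefixes with the
adapter, with optional substitution errors, and supports exact per-site
read counts so printed tallies can be used as inputs.

Uniform base composition, independent genes, equal library sizes on
average, and error-free or low-error reads are all idealizations: passing
tests demonstrate correctness of the algorithms under the stated models,
not performance on real transcriptomes, where composition bias,
correlated expression, batch effects, and alignment artifacts add error
modes the generators do not emulate. In particular the study-scale
stand-ins (the dual-endomotif transcript, the 54-transcript cohort, the
69- and 71-read fragment sets) reproduce dimensions and tallies by
construction; what they verify is that the pipeline recovers those
numbers from raw synthetic inputs end to end.

## Problem sizes

Default suites use: 200 oracle windows (≤40 nt), 100 implant-recovery
transcripts (300 nt), a 2,000-gene dual-assay simulation (24 samples),
a 1-kb fragment round-trip (999 boundaries), 54 cohort transcripts, and
69/71-read cleavage sets — sizes at which every result is stable across
seeds while the whole suite runs in seconds.
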