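"""Integrated RNAseq/GROseq decay-candidate filtering.

Steady-state RNA abundance (RNAseq) confounds mRNA decay with reduced
transcription; nascent-transcript profiling (GROseq) resolves the two.
The experimental design crosses genotype (IRE1α wild-type vs knockout)
with ER-stress treatment (Tg 8 h vs DMSO vehicle) in both assays. The
module provides:

- TMM-style between-sample scaling factors and CPM expression filtering;
- per-gene log2 fold changes (Tg relative to DMSO) in each
  assay × genotype stratum, with a moderated t-test for the wild-type
  RNAseq contrast (empirical-Bayes variance shrinkage by method of
  moments) and Benjamini–Hochberg FDR;
- the four/five-criterion removal chain that retains genes whose
  steady-state abundance drops IRE1α-dependently under stress without a
  matching decline in nascent transcription — the decay candidates.

Differential statistics are deliberately simple (log-CPM group means and
a moderated t); the bespoke contribution is the filter chain, and the
stats table can be supplied precomputed to bypass the built-in model.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from riddkit.errors import (
    DegenerateInputError,
    IncompleteStatsError,
    InsufficientReplicationError,
)


class Assay(enum.Enum):
    RNASEQ = "RNASEQ"
    GROSEQ = "GROSEQ"


#: Required sample-metadata columns.
META_COLUMNS = ("sample", "genotype", "treatment", "replicate")
GENOTYPES = ("WT", "KO")
TREATMENTS = ("DMSO", "TG8H")


@dataclass
class CountMatrix:
    """A gene × sample matrix of non-negative integer read counts.

    ``counts`` is indexed by gene id with one column per sample;
    ``metadata`` is indexed by sample with columns genotype (WT/KO),
    treatment (DMSO/TG8H) and replicate.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    assay: Assay

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            if not np.allclose(self.counts.values, np.round(self.counts.values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def genes(self) -> List[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def stratum_samples(self, genotype: str, treatment: str) -> List[str]:
        md = self.metadata
        sel = (md["genotype"] == genotype) & (md["treatment"] == treatment)
        return list(md.index[sel])


@dataclass(frozen=True)
class DEConfig:
    """Normalization and differential-statistics settings."""

    cpm_threshold: float = 1.0
    cpm_min_samples: int = 3
    prior_count: float = 0.5
    moderation: bool = True
    tmm_logratio_trim: float = 0.30
    tmm_abs_trim: float = 0.05

    def __post_init__(self) -> None:
        if self.cpm_threshold <= 0 or self.prior_count <= 0:
            raise ValueError("thresholds must be positive")
        for t in (self.tmm_logratio_trim, self.tmm_abs_trim):
            if not (0 <= t < 0.5):
                raise ValueError("trims must lie in [0, 0.5)")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the decay-candidate removal chain.

    Criteria (all must hold for a survivor):

    1. significance: p and BH-FDR of the WT RNAseq contrast ≤ ``sig_alpha``;
    2. IRE1α dependence: log2FC(KO) − log2FC(WT) in RNAseq ≥
       ``min_ko_minus_wt``;
    3. expression: average log-CPM ≥ ``min_avg_expr``;
    4. decay vs transcription: log2FC(WT RNAseq) − log2FC(WT GROseq) ≤
       ``rna_minus_gro_cut`` (steady state falls below nascent);
       ``literal_sign_mode`` flips the comparison to ≥, the literal
       reading of the removal rule this chain derives from;
    5. optional fold criterion: log2FC(WT RNAseq) ≤ −log2(``wt_fold_cut``).
    """

    sig_alpha: float = 0.05
    min_ko_minus_wt: float = 0.5
    min_avg_expr: float = 1.0
    rna_minus_gro_cut: float = -0.3
    wt_fold_cut: Optional[float] = 1.4
    literal_sign_mode: bool = False

    def __post_init__(self) -> None:
        if self.wt_fold_cut is not None and self.wt_fold_cut <= 1:
            raise ValueError("wt_fold_cut must be > 1")


#: Columns of a complete per-gene contrast-statistics table.
STATS_COLUMNS = (
    "log2fc_wt_rna", "p_wt_rna", "fdr_wt_rna",
    "log2fc_ko_rna", "log2fc_wt_gro", "log2fc_ko_gro", "avg_expr",
)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order preserved.

    Raises on p-values outside [0, 1]; q ≥ p elementwise.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def tmm_norm_factors(counts: CountMatrix, config: DEConfig = DEConfig()) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the across-sample mean. Each sample's factor is the
    (precision-weighted) mean of its per-gene log2 count ratios to the
    reference, after trimming ``tmm_logratio_trim`` at each log-ratio
    tail and ``tmm_abs_trim`` at each absolute-expression tail; factors
    are rescaled to multiply to 1. A factor > 1 marks a sample of
    relatively higher abundance, so dividing counts by the factors
    equalizes samples.
    """
    X = counts.counts.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise DegenerateInputError("TMM needs at least two samples")
    libsize = X.sum(axis=0)
    if (libsize == 0).any():
        raise DegenerateInputError("all-zero sample column")
    if n_genes < 2:
        raise DegenerateInputError("TMM needs at least two genes (nothing to trim)")

    q75 = np.array([np.quantile(X[:, s] / libsize[s], 0.75) for s in range(n_samples)])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_factors = np.zeros(n_samples)
    for s in range(n_samples):
        if s == ref:
            continue
        x, r = X[:, s], X[:, ref]
        keep = (x > 0) & (r > 0)
        if keep.sum() == 0:
            raise DegenerateInputError(
                f"no genes co-expressed between sample {counts.samples[s]!r} and reference"
            )
        x, r = x[keep], r[keep]
        m = np.log2(x / r)                      # log-ratio
        a = 0.5 * (np.log2(x * r))              # absolute expression
        # asymptotic precision weights (delta method on the log-ratio)
        w = 1.0 / ((libsize[s] - x) / (libsize[s] * x) + (libsize[ref] - r) / (libsize[ref] * r))

        lo_m, hi_m = np.quantile(m, [config.tmm_logratio_trim, 1 - config.tmm_logratio_trim])
        lo_a, hi_a = np.quantile(a, [config.tmm_abs_trim, 1 - config.tmm_abs_trim])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not sel.any():
            sel = np.ones_like(m, dtype=bool)
        log_factors[s] = np.average(m[sel], weights=w[sel])

    log_factors -= log_factors.mean()           # product of factors = 1
    return pd.Series(2.0 ** log_factors, index=counts.samples, name="norm_factor")


def filter_expressed(counts: CountMatrix, config: DEConfig = DEConfig()) -> CountMatrix:
    """Keep genes with CPM above threshold in enough samples.

    CPM uses raw library sizes (pre-normalization); the sample set is
    unchanged.
    """
    keep = expressed_genes([counts], config)
    return CountMatrix(
        counts=counts.counts.loc[counts.counts.index.isin(keep)],
        metadata=counts.metadata,
        assay=counts.assay,
    )


def expressed_genes(matrices: Sequence[CountMatrix], config: DEConfig = DEConfig()) -> List[str]:
    """Genes passing the CPM filter on the column-concatenated matrices.

    Mirrors running the expression filter on a single dataset formed by
    concatenating all assays' samples.
    """
    cpms = []
    for cm in matrices:
        X = cm.counts.to_numpy(dtype=float)
        cpms.append(pd.DataFrame(
            X / X.sum(axis=0, keepdims=True) * 1e6,
            index=cm.counts.index, columns=cm.counts.columns,
        ))
    joint = pd.concat(cpms, axis=1)
    ok = (joint > config.cpm_threshold).sum(axis=1) >= config.cpm_min_samples
    return [g for g in matrices[0].genes if ok.get(g, False)]


def log_cpm(counts: CountMatrix, config: DEConfig = DEConfig(),
            norm_factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """Prior-count-stabilized log2 counts-per-million.

    When TMM factors are given, effective library sizes are the factors
    scaled to the geometric mean of the raw library sizes (the factors
    already capture each sample's relative abundance); the prior count
    keeps zero-count genes finite.
    """
    X = counts.counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if norm_factors is not None:
        nf = norm_factors.loc[counts.samples].to_numpy()
        lib = nf * np.exp(np.mean(np.log(lib)))
    prior = config.prior_count * lib / lib.mean()   # library-size-scaled prior
    vals = np.log2((X + prior) / (lib + 2 * prior) * 1e6)
    return pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)


def _moderate_variances(s2: np.ndarray, df: int) -> Tuple[np.ndarray, float]:
    """Empirical-Bayes shrink per-gene variances toward a common prior.

    Method-of-moments fit of a scaled inverse-chi-square prior to the
    marginal distribution of the sample variances (marginally
    ``s0^2 · F(df, d0)``); returns the posterior-mean variances and the
    prior degrees of freedom ``d0``.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return s2, 0.0
    M = positive.mean()
    V = positive.var(ddof=1)
    r = V / (M * M) if M > 0 else np.inf
    if r * df <= 2:
        d0 = math.inf
    else:
        d0 = (4 * r * df + 2 * df - 4) / (r * df - 2)
        if d0 <= 4:
            d0 = 4.0
    if math.isinf(d0):
        s0_2 = M
        return np.full_like(s2, s0_2), d0
    s0_2 = M * (d0 - 2) / d0
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def de_stats(
    rna: CountMatrix,
    gro: CountMatrix,
    de_cfg: DEConfig = DEConfig(),
) -> pd.DataFrame:
    """Per-gene contrast statistics for the decay filter.

    For each assay × genotype stratum the log2 fold change is the mean
    log-CPM difference (Tg 8 h minus DMSO). The wild-type RNAseq contrast
    additionally carries a two-sided t-test — moderated via
    empirical-Bayes variance shrinkage when ``de_cfg.moderation`` — and a
    BH FDR. ``avg_expr`` is the grand mean log-CPM over all samples of
    both assays. Returns a DataFrame indexed by gene with columns
    :data:`STATS_COLUMNS` plus a ``degenerate`` flag for zero-variance
    genes whose p-value defaults to 1.
    """
    if list(rna.counts.index) != list(gro.counts.index):
        raise IncompleteStatsError("RNAseq and GROseq gene sets must match (same order)")
    for cm in (rna, gro):
        for gt in GENOTYPES:
            for tr in TREATMENTS:
                n = len(cm.stratum_samples(gt, tr))
                if n < 2:
                    raise InsufficientReplicationError(
                        f"stratum ({cm.assay.value}, {gt}, {tr}) has {n} replicate(s); need >= 2"
                    )

    lc = {
        Assay.RNASEQ: log_cpm(rna, de_cfg, tmm_norm_factors(rna, de_cfg)),
        Assay.GROSEQ: log_cpm(gro, de_cfg, tmm_norm_factors(gro, de_cfg)),
    }
    matrices = {Assay.RNASEQ: rna, Assay.GROSEQ: gro}

    out = pd.DataFrame(index=rna.counts.index)
    for assay, tag in ((Assay.RNASEQ, "rna"), (Assay.GROSEQ, "gro")):
        cm = matrices[assay]
        for gt in GENOTYPES:
            tg = lc[assay][cm.stratum_samples(gt, "TG8H")]
            dmso = lc[assay][cm.stratum_samples(gt, "DMSO")]
            out[f"log2fc_{gt.lower()}_{tag}"] = tg.mean(axis=1) - dmso.mean(axis=1)

    # Wild-type RNAseq test: two-group comparison on log-CPM.
    tg_cols = rna.stratum_samples("WT", "TG8H")
    dm_cols = rna.stratum_samples("WT", "DMSO")
    tg = lc[Assay.RNASEQ][tg_cols].to_numpy()
    dm = lc[Assay.RNASEQ][dm_cols].to_numpy()
    n1, n2 = tg.shape[1], dm.shape[1]
    diff = tg.mean(axis=1) - dm.mean(axis=1)
    df_resid = n1 + n2 - 2
    pooled = ((n1 - 1) * tg.var(axis=1, ddof=1) + (n2 - 1) * dm.var(axis=1, ddof=1)) / df_resid
    pooled = np.where(pooled < 1e-20, 0.0, pooled)  # clamp rounding-level variances
    degenerate = pooled <= 0

    if de_cfg.moderation:
        s2, d0 = _moderate_variances(pooled, df_resid)
        dof = df_resid + (0 if math.isinf(d0) else d0)
        if math.isinf(d0):
            dof = 1e6  # effectively normal
    else:
        s2, dof = pooled, df_resid
    se = np.sqrt(s2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, diff / se, 0.0)
    p = 2 * sps.t.sf(np.abs(tstat), dof)
    p = np.where((se <= 0), 1.0, p)
    p = np.where(degenerate & ~de_cfg.moderation, 1.0, p)
    p = np.clip(p, 0.0, 1.0)

    out["p_wt_rna"] = p
    out["fdr_wt_rna"] = bh_fdr(p)
    out["avg_expr"] = pd.concat([lc[Assay.RNASEQ], lc[Assay.GROSEQ]], axis=1).mean(axis=1)
    out["degenerate"] = degenerate
    return out[list(STATS_COLUMNS) + ["degenerate"]]


@dataclass
class FilterResult:
    """Per-criterion pass flags and the surviving decay candidates."""

    flags: pd.DataFrame
    survivors: List[str] = field(default_factory=list)


def apply_filter_chain(stats: pd.DataFrame, config: FilterConfig = FilterConfig()) -> FilterResult:
    """Apply the decay-candidate removal chain to a stats table.

    Survivors are the genes passing every enabled criterion (see
    :class:`FilterConfig`); per-criterion boolean flags are always
    populated so the criteria can be audited independently. The order in
    which criteria are evaluated is irrelevant: the survivor set is the
    intersection of the per-criterion pass sets.
    """
    missing = [c for c in STATS_COLUMNS if c not in stats.columns]
    if missing:
        raise IncompleteStatsError(f"stats table missing columns: {missing}")
    if stats[list(STATS_COLUMNS)].isna().any().any():
        bad = stats.index[stats[list(STATS_COLUMNS)].isna().any(axis=1)][:5]
        raise IncompleteStatsError(f"stats table has missing values (e.g. genes {list(bad)})")

    flags = pd.DataFrame(index=stats.index)
    flags["pass_sig"] = (stats["p_wt_rna"] <= config.sig_alpha) & (
        stats["fdr_wt_rna"] <= config.sig_alpha
    )
    flags["pass_ko_wt"] = (
        stats["log2fc_ko_rna"] - stats["log2fc_wt_rna"] >= config.min_ko_minus_wt
    )
    flags["pass_avg_expr"] = stats["avg_expr"] >= config.min_avg_expr
    delta = stats["log2fc_wt_rna"] - stats["log2fc_wt_gro"]
    if config.literal_sign_mode:
        flags["pass_rna_gro"] = delta >= config.rna_minus_gro_cut
    else:
        flags["pass_rna_gro"] = delta <= config.rna_minus_gro_cut
    if config.wt_fold_cut is not None:
        flags["pass_fold"] = stats["log2fc_wt_rna"] <= -math.log2(config.wt_fold_cut)
    else:
        flags["pass_fold"] = True

    survivors = list(flags.index[flags.all(axis=1)])
    return FilterResult(flags=flags, survivors=survivors)


# ---------------------------------------------------------------------------
# TSV interfaces

def read_counts_tsv(counts_path, meta_path, assay: Assay) -> CountMatrix:
    """Load a counts TSV (gene id column + sample columns) with metadata."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise IncompleteStatsError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("sample")
    if "assay" in meta.columns:
        meta = meta[meta["assay"] == assay.value]
    keep = [s for s in counts.columns if s in meta.index]
    return CountMatrix(counts=counts[keep], metadata=meta.loc[keep], assay=assay)
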