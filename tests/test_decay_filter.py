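"""Normalization, differential statistics, and the decay filter chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle import step_up_fdr
from riddkit.decay_filter import (
    Assay,
    CountMatrix,
    DEConfig,
    FilterConfig,
    apply_filter_chain,
    bh_fdr,
    de_stats,
    expressed_genes,
    filter_expressed,
    log_cpm,
    tmm_norm_factors,
)
from riddkit.errors import (
    DegenerateInputError,
    IncompleteStatsError,
    InsufficientReplicationError,
)
from riddkit.synthetic_fixtures import CountSimSpec, make_count_dataset


def _matrix(columns, index=None, genotype=None, treatment=None):
    counts = pd.DataFrame(columns, index=index)
    n = counts.shape[1]
    meta = pd.DataFrame(
        {
            "genotype": genotype or ["WT"] * n,
            "treatment": treatment or ["DMSO"] * n,
            "replicate": list(range(1, n + 1)),
        },
        index=list(counts.columns),
    )
    return CountMatrix(counts=counts, metadata=meta, assay=Assay.RNASEQ)


class TestTMM:
    def test_identical_columns_get_unit_factors(self):
        cm = _matrix({"a": [10, 20, 30, 40] * 5, "b": [10, 20, 30, 40] * 5})
        assert np.allclose(tmm_norm_factors(cm).values, [1.0, 1.0])

    def test_uniform_doubling_splits_geometrically(self):
        base = list(range(10, 50))
        cm = _matrix({"a": [2 * x for x in base], "b": base})
        f = tmm_norm_factors(cm)
        assert np.allclose(f.values, [np.sqrt(2), 1 / np.sqrt(2)], atol=1e-6)
        assert np.isclose(f.prod(), 1.0)

    def test_single_gene_matrix_is_degenerate(self):
        cm = _matrix({"a": [5], "b": [7]})
        with pytest.raises(DegenerateInputError):
            tmm_norm_factors(cm)

    def test_all_zero_sample_is_degenerate(self):
        cm = _matrix({"a": [5, 5, 5], "b": [0, 0, 0]})
        with pytest.raises(DegenerateInputError):
            tmm_norm_factors(cm)

    def test_factors_equalize_scaled_libraries_in_log_cpm(self):
        base = list(range(10, 50))
        cm = _matrix({"a": [2 * x for x in base], "b": base})
        lc = log_cpm(cm, DEConfig(), tmm_norm_factors(cm))
        assert np.allclose(lc["a"], lc["b"], atol=1e-6)


class TestExpressionFilter:
    def test_cpm_threshold_and_sample_count_rule(self):
        # every library sums to exactly 1e6 so CPM equals the raw count
        cols = {}
        for s in range(12):
            row = [2 if s < 3 else 0, 1, 5 if s < 2 else 0]
            cols[f"s{s}"] = row + [1_000_000 - sum(row)]
        cm = _matrix(cols, index=["just_above", "at_threshold", "two_samples", "big"])
        kept = filter_expressed(cm, DEConfig())
        assert "just_above" in kept.genes          # CPM 2 > 1 in 3 samples
        assert "at_threshold" not in kept.genes    # CPM exactly 1 never exceeds 1
        assert "two_samples" not in kept.genes     # above threshold in only 2 samples
        assert kept.samples == cm.samples

    def test_joint_filter_matches_concatenated_counting(self):
        spec = CountSimSpec(n_genes=300, seed=9)
        rna, gro, _ = make_count_dataset(spec)
        keep = expressed_genes([rna, gro])
        assert set(keep) <= set(rna.genes)
        assert len(keep) > 0


class TestBH:
    def test_hand_step_up_examples(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(bh_fdr([1.0]), [1.0])
        assert np.allclose(bh_fdr([0.5, 0.5]), [0.5, 0.5])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_step_up_and_dominates_p(self, pvals):
        q = bh_fdr(pvals)
        assert np.allclose(q, step_up_fdr(pvals))
        assert (q >= np.asarray(pvals) - 1e-12).all()

    def test_order_invariance(self):
        p = [0.9, 0.001, 0.04, 0.5, 0.04]
        q = bh_fdr(p)
        perm = [3, 0, 4, 1, 2]
        q_perm = bh_fdr([p[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm)


def _paired_dataset(**kwargs):
    spec = CountSimSpec(**kwargs)
    rna, gro, truth = make_count_dataset(spec)
    keep = expressed_genes([rna, gro])
    rna.counts = rna.counts.loc[keep]
    gro.counts = gro.counts.loc[keep]
    return rna, gro, truth


class TestDEStats:
    def test_identical_groups_give_null_contrast(self):
        rna, gro, _ = _paired_dataset(n_genes=50, n_implanted_ridd=0,
                                      n_transcriptional=0, n_ire1_independent=0, seed=2)
        # make every WT RNAseq column identical, so DMSO and Tg agree exactly
        wt = [c for c in rna.samples if c.startswith("rna_wt")]
        for c in wt[1:]:
            rna.counts[c] = rna.counts[wt[0]]
        stats = de_stats(rna, gro)
        assert stats["log2fc_wt_rna"].abs().max() == pytest.approx(0.0, abs=1e-9)
        assert stats["p_wt_rna"].min() == pytest.approx(1.0, abs=1e-6)

    def test_two_fold_decrease_estimated_within_tolerance_at_low_dispersion(self):
        """log2FC of a true 2-fold decrease lands within ±0.3 for ≥95% of genes."""
        # implants kept to 5% of genes so scaling normalization stays valid
        rna, gro, truth = _paired_dataset(
            n_genes=2500, n_implanted_ridd=125, n_transcriptional=0,
            n_ire1_independent=0, nb_dispersion=0.005, baseline_log2_mean=10.0, seed=4,
        )
        stats = de_stats(rna, gro)
        implanted = [g for g in truth.gene[truth.cls == "ridd"] if g in stats.index]
        err = (stats.loc[implanted, "log2fc_wt_rna"] + 1.0).abs()
        assert (err <= 0.3).mean() >= 0.95

    def test_zero_variance_gene_without_moderation_reports_p_one(self):
        rna, gro, _ = _paired_dataset(n_genes=50, n_implanted_ridd=0,
                                      n_transcriptional=0, n_ire1_independent=0, seed=2)
        wt = [c for c in rna.samples if c.startswith("rna_wt")]
        for c in wt[1:]:
            rna.counts[c] = rna.counts[wt[0]]
        stats = de_stats(rna, gro, DEConfig(moderation=False))
        assert stats["degenerate"].all()
        assert (stats["p_wt_rna"] == 1.0).all()

    def test_missing_replicates_error_names_stratum(self):
        rna, gro, _ = _paired_dataset(n_genes=30, n_implanted_ridd=0,
                                      n_transcriptional=0, n_ire1_independent=0, seed=2)
        drop = [c for c in rna.samples if c.startswith("rna_ko_tg8h")][1:]
        rna.counts = rna.counts.drop(columns=drop)
        rna.metadata = rna.metadata.drop(index=drop)
        with pytest.raises(InsufficientReplicationError, match="KO"):
            de_stats(rna, gro)

    def test_fdr_dominates_p(self):
        rna, gro, _ = _paired_dataset(n_genes=200, seed=6)
        stats = de_stats(rna, gro)
        assert (stats["fdr_wt_rna"] >= stats["p_wt_rna"] - 1e-12).all()
        assert np.isfinite(stats["avg_expr"]).all()


STATS_A = dict(
    log2fc_wt_rna=-1.0, p_wt_rna=0.01, fdr_wt_rna=0.03,
    log2fc_ko_rna=0.0, log2fc_wt_gro=-0.1, log2fc_ko_gro=0.0, avg_expr=5.0,
)


def _stats_frame(**overrides):
    rows = {"geneA": dict(STATS_A)}
    for name, changes in overrides.items():
        row = dict(STATS_A)
        row.update(changes)
        rows[name] = row
    return pd.DataFrame(rows).T


class TestFilterChain:
    def test_hand_applied_thresholds(self):
        stats = _stats_frame(
            geneB={"p_wt_rna": 0.2},
            geneC={"log2fc_ko_rna": -0.9},
        )
        result = apply_filter_chain(stats, FilterConfig())
        assert result.survivors == ["geneA"]
        assert not result.flags.loc["geneB", "pass_sig"]
        assert not result.flags.loc["geneC", "pass_ko_wt"]
        assert result.flags.loc["geneA"].all()

    def test_literal_sign_mode_flips_decay_criterion(self):
        stats = _stats_frame(geneD={"log2fc_wt_gro": -2.0})  # rna - gro = +1.0
        default = apply_filter_chain(stats, FilterConfig())
        literal = apply_filter_chain(stats, FilterConfig(literal_sign_mode=True))
        assert "geneD" not in default.survivors
        assert "geneD" in literal.survivors

    def test_fold_criterion_can_be_disabled(self):
        stats = _stats_frame(geneE={"log2fc_wt_rna": -0.4, "log2fc_ko_rna": 0.2})
        with_fold = apply_filter_chain(stats, FilterConfig())
        without = apply_filter_chain(stats, FilterConfig(wt_fold_cut=None))
        assert "geneE" not in with_fold.survivors  # -0.4 > -log2(1.4)
        assert "geneE" in without.survivors

    def test_survivors_are_intersection_of_criteria(self):
        stats = _stats_frame(
            geneB={"p_wt_rna": 0.2}, geneC={"avg_expr": 0.5}, geneD={"log2fc_wt_gro": -1.0}
        )
        result = apply_filter_chain(stats)
        for gene in stats.index:
            assert (gene in result.survivors) == bool(result.flags.loc[gene].all())

    def test_tightening_thresholds_never_grows_survivor_set(self):
        rng = np.random.default_rng(12)
        stats = pd.DataFrame(
            {
                "log2fc_wt_rna": rng.normal(-0.6, 0.8, 200),
                "p_wt_rna": rng.uniform(0, 0.2, 200),
                "log2fc_ko_rna": rng.normal(0, 0.5, 200),
                "log2fc_wt_gro": rng.normal(0, 0.5, 200),
                "log2fc_ko_gro": rng.normal(0, 0.5, 200),
                "avg_expr": rng.uniform(0, 8, 200),
            },
            index=[f"g{i}" for i in range(200)],
        )
        stats["fdr_wt_rna"] = bh_fdr(stats["p_wt_rna"])
        base = set(apply_filter_chain(stats, FilterConfig()).survivors)
        tighter = [
            FilterConfig(sig_alpha=0.01),
            FilterConfig(min_ko_minus_wt=0.8),
            FilterConfig(min_avg_expr=2.0),
            FilterConfig(rna_minus_gro_cut=-0.6),
            FilterConfig(wt_fold_cut=2.0),
        ]
        for cfg in tighter:
            assert set(apply_filter_chain(stats, cfg).survivors) <= base

    def test_missing_column_raises(self):
        stats = _stats_frame().drop(columns=["avg_expr"])
        with pytest.raises(IncompleteStatsError, match="avg_expr"):
            apply_filter_chain(stats)

    def test_null_simulation_yields_few_survivors(self):
        rna, gro, _ = _paired_dataset(
            n_genes=800, n_implanted_ridd=0, n_transcriptional=0,
            n_ire1_independent=0, seed=8,
        )
        stats = de_stats(rna, gro)
        result = apply_filter_chain(stats)
        assert len(result.survivors) <= 2

    def test_non_decay_classes_are_rejected(self):
        """Transcriptional and IRE1-independent genes never survive the chain."""
        rna, gro, truth = _paired_dataset(
            n_genes=600, n_implanted_ridd=8, n_transcriptional=8,
            n_ire1_independent=8, nb_dispersion=1e-4,
            baseline_log2_mean=10.0, baseline_log2_sd=0.5, seed=10,
        )
        stats = de_stats(rna, gro)
        survivors = set(apply_filter_chain(stats).survivors)
        confounders = set(truth.gene[truth.cls.isin(["transcriptional", "ire1_independent"])])
        assert survivors.isdisjoint(confounders)
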