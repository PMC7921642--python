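"""Differential-expression module: pooled/moderated t, BH, filtering, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stagesig import (
    ContrastError,
    DegenerateDataError,
    SimulationConfig,
    StageDesign,
    ValidationError,
    simulate_expression,
)
from stagesig import dge


def _two_group_design(n_ctrl, n_stage):
    assignment = {f"c{i}": "ctrl" for i in range(n_ctrl)}
    assignment.update({f"t{i}": "tumor" for i in range(n_stage)})
    return StageDesign(assignment=assignment, stage_order=("ctrl", "tumor"),
                       control_stages=("ctrl",))


def _expr(ctrl_rows, stage_rows, gene_ids=None):
    ctrl = np.atleast_2d(np.asarray(ctrl_rows, float))
    stage = np.atleast_2d(np.asarray(stage_rows, float))
    genes = gene_ids or [f"g{i}" for i in range(ctrl.shape[0])]
    cols = [f"c{i}" for i in range(ctrl.shape[1])] + [f"t{i}" for i in range(stage.shape[1])]
    return pd.DataFrame(np.hstack([ctrl, stage]), index=genes, columns=cols)


class TestFitContrast:
    def test_hand_computed_pooled_t(self):
        # control (1,2,3) vs stage (4,5,6): diff 3, pooled s^2 = 1,
        # t = 3 / sqrt(2/3) = 3.674, df = 4.
        expr = _expr([[1, 2, 3]], [[4, 5, 6]])
        design = _two_group_design(3, 3)
        table = dge.fit_contrast(expr, design, "tumor", moderated=False)
        row = table.iloc[0]
        assert row["mean_stage"] - row["mean_control"] == pytest.approx(3.0)
        assert row["t"] == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-6)
        assert table.attrs["df"] == 4
        assert row["p"] == pytest.approx(2 * stats.t.sf(3 / np.sqrt(2 / 3), 4), abs=1e-9)

    def test_unmoderated_matches_scipy_pooled_t(self, rng):
        ctrl = rng.normal(0, 1, (40, 6))
        stage = rng.normal(0.3, 1, (40, 5))
        expr = _expr(ctrl, stage)
        table = dge.fit_contrast(expr, _two_group_design(6, 5), "tumor", moderated=False)
        ref = stats.ttest_ind(stage, ctrl, axis=1, equal_var=True)
        assert np.allclose(table["t"], ref.statistic, atol=1e-10)
        assert np.allclose(table["p"], ref.pvalue, atol=1e-10)

    def test_identical_groups_give_null_result(self, rng):
        vals = rng.normal(5, 1, (10, 4))
        expr = _expr(vals, vals.copy())
        table = dge.fit_contrast(expr, _two_group_design(4, 4), "tumor", moderated=False)
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_moderated_t_shrinks_toward_prior(self, rng):
        # A gene with tiny sample variance gets a larger moderated than raw
        # denominator when the prior variance is larger.
        ctrl = rng.normal(0, 1, (500, 8))
        stage = rng.normal(0, 1, (500, 8))
        ctrl[0] *= 0.01
        stage[0] = ctrl[0] + 0.5  # small variance, real shift
        expr = _expr(ctrl, stage)
        design = _two_group_design(8, 8)
        raw = dge.fit_contrast(expr, design, "tumor", moderated=False)
        mod = dge.fit_contrast(expr, design, "tumor", moderated=True)
        assert mod.attrs["d0"] > 0
        assert abs(mod["t"].iloc[0]) < abs(raw["t"].iloc[0])

    def test_moderation_hyperparameters_recovered(self, rng):
        # Variances drawn from the scaled inverse-chi-square prior the
        # moment estimator assumes: d0 = 8, s0^2 = 2, d_g = 10.
        d0, s02, dg, n = 8.0, 2.0, 10, 20000
        sigma2 = d0 * s02 / stats.chi2.rvs(d0, size=n, random_state=rng)
        s2 = sigma2 * stats.chi2.rvs(dg, size=n, random_state=rng) / dg
        fit = dge.fit_moderation(s2, dg)
        assert fit.d0 == pytest.approx(d0, rel=0.15)
        assert fit.s02 == pytest.approx(s02, rel=0.1)

    def test_contrast_errors(self, rng):
        expr = _expr(rng.normal(size=(5, 4)), rng.normal(size=(5, 4)))
        design = _two_group_design(4, 4)
        with pytest.raises(ContrastError):
            dge.fit_contrast(expr, design, "ctrl")
        with pytest.raises(ContrastError):
            dge.fit_contrast(expr, design, "missing-stage")
        tiny = _expr(rng.normal(size=(5, 4)), rng.normal(size=(5, 1)))
        with pytest.raises(ContrastError, match=">= 2 samples"):
            dge.fit_contrast(tiny, _two_group_design(4, 1), "tumor")

    def test_all_zero_variance_is_degenerate(self):
        expr = _expr(np.ones((3, 4)), np.full((3, 3), 2.0))
        with pytest.raises(DegenerateDataError):
            dge.fit_contrast(expr, _two_group_design(4, 3), "tumor", moderated=True)


class TestBHAdjust:
    def test_step_up_hand_example(self):
        out = dge.bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04])

    def test_edge_cases(self):
        assert np.allclose(dge.bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert dge.bh_adjust([0.123])[0] == pytest.approx(0.123)
        with pytest.raises(ValidationError):
            dge.bh_adjust([0.5, 1.5])
        with pytest.raises(ValidationError):
            dge.bh_adjust([-0.1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40), st.randoms())
    def test_permutation_equivariance(self, pvals, pyrandom):
        p = np.asarray(pvals)
        perm = np.arange(p.size)
        pyrandom.shuffle(perm)
        direct = dge.bh_adjust(p)[perm]
        permuted = dge.bh_adjust(p[perm])
        assert np.allclose(direct, permuted)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_monotone(self, pvals):
        p = np.asarray(pvals)
        adj = dge.bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


def _toy_table(genes, fcs, adj_ps, contrast):
    table = pd.DataFrame(
        {
            "mean_stage": 0.0,
            "mean_control": 0.0,
            "signed_fc": fcs,
            "t": 0.0,
            "p": adj_ps,
            "adj_p": adj_ps,
        },
        index=pd.Index(genes),
    )
    table.attrs["contrast"] = contrast
    return table


class TestFilterAndMerge:
    def test_both_thresholds_applied(self):
        table = _toy_table(["a", "b", "c"], [2.0, -1.2, -1.8], [0.01, 0.01, 0.2], "x")
        merged = dge.filter_and_merge([table])
        assert list(merged["gene"]) == ["a"]

    def test_union_with_provenance(self):
        t1 = _toy_table(["a", "b"], [2.0, 1.0], [0.01, 0.5], "s1")
        t2 = _toy_table(["a", "b"], [2.0, -3.0], [0.01, 0.001], "s2")
        merged = dge.filter_and_merge({"s1": t1, "s2": t2})
        assert list(merged["gene"]) == ["a", "b"]
        row_a = merged.set_index("gene").loc["a"]
        assert row_a["contrasts"] == "s1,s2"
        assert row_a["n_contrasts"] == 2

    def test_all_fail_gives_empty(self):
        table = _toy_table(["a", "b"], [1.0, -1.0], [0.9, 0.9], "x")
        assert len(dge.filter_and_merge([table])) == 0

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            dge.filter_and_merge([])

    def test_monotone_in_thresholds(self, rng):
        genes = [f"g{i}" for i in range(60)]
        table = _toy_table(
            genes,
            rng.uniform(-4, 4, 60),
            rng.uniform(0, 1, 60),
            "x",
        )
        loose = set(dge.filter_and_merge([table], p_thresh=0.2, fc_thresh=1.2)["gene"])
        tighter_fc = set(dge.filter_and_merge([table], p_thresh=0.2, fc_thresh=2.0)["gene"])
        tighter_p = set(dge.filter_and_merge([table], p_thresh=0.05, fc_thresh=1.2)["gene"])
        assert tighter_fc <= loose
        assert tighter_p <= loose


def test_signed_fold_change_convention():
    # log2 difference of +1 -> fold change 2; -1 -> -2; 0 -> 1 (no change).
    fc = dge.signed_fold_change(np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    assert np.allclose(fc, [2.0, -2.0, 1.0])


def test_planted_gene_recovery():
    """Parameter recovery at the oracle-fixed conditions: effect 2, noise 1,
    15 samples/stage, 50 planted of 1000 with an independent background."""
    cfg = SimulationConfig(
        n_genes=1000, n_signature=50, samples_per_stage=(15,) * 8,
        effect_size=2.0, noise_sd=1.0, n_modules=0, seed=0,
    )
    expr, design, truth = simulate_expression(cfg)
    merged = set(dge.filter_and_merge(dge.fit_all_contrasts(expr, design))["gene"])
    tp = len(merged & truth.signature_genes)
    fp = len(merged) - tp
    assert tp / 50 >= 0.9
    assert fp / max(len(merged), 1) <= 0.25  # union of six BH-0.05 contrasts


def test_collapse_to_symbols_keeps_max_abs_t():
    table = _toy_table(["p1", "p2", "p3"], [2.0, 2.0, 2.0], [0.01] * 3, "x")
    table["t"] = [1.0, -5.0, 2.0]
    out = dge.collapse_to_symbols(table, {"p1": "GENEA", "p2": "GENEA"})
    assert list(out.index) == ["GENEA"]
    assert out.loc["GENEA", "t"] == -5.0
    assert out.attrs["unmapped_probes"] == 1
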