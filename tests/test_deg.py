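import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosskey.deg import (
    EBayesHyperparams,
    ExpressionDataset,
    bh_adjust,
    collapse_probes,
    deg_table,
    filter_degs,
    moderated_t_test,
    preprocess,
    quantile_normalize,
)


def _dataset(case_rows, ctrl_rows, index=None):
    case = np.atleast_2d(case_rows)
    ctrl = np.atleast_2d(ctrl_rows)
    cols = [f"c{i}" for i in range(case.shape[1])] + [f"n{i}" for i in range(ctrl.shape[1])]
    values = pd.DataFrame(np.hstack([case, ctrl]), columns=cols, index=index)
    groups = pd.Series(
        ["case"] * case.shape[1] + ["control"] * ctrl.shape[1], index=cols
    )
    return ExpressionDataset(values=values, groups=groups)


class TestQuantileNormalization:
    def test_hand_computed_two_column_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = quantile_normalize(df)
        # row-wise sorted means are (mean(1,3), mean(2,4)) = (2, 3)
        assert out["a"].tolist() == [2.0, 3.0]
        assert out["b"].tolist() == [2.0, 3.0]

    def test_identical_columns_are_a_fixed_point(self):
        df = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_all_columns_share_sorted_values(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        out = quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(30, 5)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_ties_receive_average_of_spanned_quantile_means(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [10.0, 20.0, 30.0]})
        out = quantile_normalize(df)
        sorted_means = [(1 + 10) / 2, (1 + 20) / 2, (2 + 30) / 2]
        assert out["a"].iloc[0] == pytest.approx((sorted_means[0] + sorted_means[1]) / 2)
        assert out["a"].iloc[1] == out["a"].iloc[0]


class TestPreprocess:
    def test_linear_scale_detected_and_logged(self):
        raw = pd.DataFrame(
            {"c0": [1000.0, 10.0], "c1": [1000.0, 10.0], "n0": [1000.0, 10.0], "n1": [1000.0, 10.0]},
            index=["p1", "p2"],
        )
        groups = pd.Series(["case", "case", "control", "control"], index=raw.columns)
        ds = preprocess(raw, groups)
        assert ds.values.max().max() < 11  # log2(1001) ~ 9.97

    def test_log_scale_left_alone(self):
        raw = pd.DataFrame(
            np.full((2, 4), 8.0), index=["p1", "p2"],
            columns=["c0", "c1", "n0", "n1"],
        )
        groups = pd.Series(["case", "case", "control", "control"], index=raw.columns)
        ds = preprocess(raw, groups)
        assert ds.values.to_numpy().max() == pytest.approx(8.0)

    def test_non_numeric_cell_reports_coordinates(self):
        raw = pd.DataFrame(
            {"c0": [1.0, 2.0], "c1": [1.0, 2.0], "n0": [1.0, "bad"], "n1": [1.0, 2.0]},
            index=["p1", "p2"],
        )
        groups = pd.Series(["case", "case", "control", "control"], index=raw.columns)
        with pytest.raises(ValueError, match="p2.*n0"):
            preprocess(raw, groups)


class TestModeratedT:
    def test_fixed_hyperparameter_shrinkage_fixture(self):
        """Two groups (3,5) vs (0,2) with d0=4, s0^2=1: pooled s^2=2,
        posterior variance 4/3, t = 3/sqrt(4/3) ~ 2.598 on 6 df."""
        ds = _dataset([[3.0, 5.0]], [[0.0, 2.0]], index=["p"])
        res, _ = moderated_t_test(ds, EBayesHyperparams(d0=4.0, s0_sq=1.0))
        assert res.loc["p", "log2fc"] == pytest.approx(3.0)
        assert res.loc["p", "t_mod"] == pytest.approx(3.0 / math.sqrt(4.0 / 3.0), rel=1e-9)
        assert res.loc["p", "df_total"] == 6

    def test_equal_group_means_give_zero_statistic(self):
        ds = _dataset([[1.0, 3.0]], [[3.0, 1.0]], index=["p"])
        res, _ = moderated_t_test(ds, EBayesHyperparams(d0=4.0, s0_sq=1.0))
        assert res.loc["p", "t_mod"] == 0.0
        assert res.loc["p", "p"] == pytest.approx(1.0)

    def test_small_prior_df_approaches_ordinary_t(self):
        rng = np.random.default_rng(3)
        case = rng.normal(1.0, 1.0, size=(10, 6))
        ctrl = rng.normal(0.0, 1.0, size=(10, 6))
        ds = _dataset(case, ctrl)
        res, _ = moderated_t_test(ds, EBayesHyperparams(d0=1e-9, s0_sq=5.0))
        from scipy import stats

        t_ref, _ = stats.ttest_ind(case, ctrl, axis=1)
        np.testing.assert_allclose(res["t_mod"].to_numpy(), t_ref, rtol=1e-4)

    def test_infinite_prior_df_pins_variance_to_prior(self):
        rng = np.random.default_rng(4)
        case = rng.normal(0.5, 1.0, size=(5, 8))
        ctrl = rng.normal(0.0, 1.0, size=(5, 8))
        ds = _dataset(case, ctrl)
        res, _ = moderated_t_test(ds, EBayesHyperparams(d0=math.inf, s0_sq=2.0))
        expected = res["log2fc"].to_numpy() / math.sqrt(2.0 * (1 / 8 + 1 / 8))
        np.testing.assert_allclose(res["t_mod"].to_numpy(), expected)

    def test_hyperparameter_estimation_recovers_prior_scale(self):
        """Variances drawn from the scaled-F model around s0^2=0.25 should
        give an estimated prior near 0.25 with moderate d0."""
        rng = np.random.default_rng(5)
        n_genes, n = 3000, 10
        d0_true, s0_true = 8.0, 0.25
        # gene variance ~ s0^2 * d0 / chi2(d0)
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=n_genes)
        case = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n_genes, n))
        ctrl = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n_genes, n))
        ds = _dataset(case, ctrl)
        _, hyper = moderated_t_test(ds)
        assert hyper.s0_sq == pytest.approx(s0_true, rel=0.15)
        assert 4.0 < hyper.d0 < 16.0

    def test_all_zero_variance_is_an_error(self):
        ds = _dataset([[1.0, 1.0]], [[0.0, 0.0]], index=["p"])
        with pytest.raises(ValueError, match="zero within-group variance"):
            moderated_t_test(ds)

    def test_null_data_false_positive_rate_controlled(self):
        """On data with no planted effects, the fraction of genes called at
        adjusted p < 0.01 stays at or below 1% on average."""
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            case = rng.normal(0, 0.5, size=(2000, 15))
            ctrl = rng.normal(0, 0.5, size=(2000, 15))
            ds = _dataset(case, ctrl)
            res, _ = moderated_t_test(ds)
            adj = bh_adjust(res["p"].to_numpy())
            rates.append((adj < 0.01).mean())
        assert np.mean(rates) <= 0.01 + 1e-9


class TestBHAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize(
        "p,expected",
        [([0.5], [0.5]), ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])],
    )
    def test_degenerate_inputs(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_rank_monotone(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCollapseAndFilter:
    def test_minimum_adjusted_p_probe_represents_the_gene(self):
        per_probe = pd.DataFrame(
            {"log2fc": [1.0, 2.0], "adj_p": [0.02, 0.001]}, index=["pA", "pB"]
        )
        ann = pd.Series({"pA": "G1", "pB": "G1"})
        out = collapse_probes(per_probe, ann)
        assert out.loc["G1", "probe"] == "pB"
        assert out.loc["G1", "log2fc"] == 2.0

    def test_blank_symbols_dropped_and_ties_lexicographic(self):
        per_probe = pd.DataFrame(
            {"log2fc": [1.0, 2.0, 3.0], "adj_p": [0.01, 0.01, 0.5]},
            index=["pB", "pA", "pX"],
        )
        ann = pd.Series({"pB": "G1", "pA": "G1", "pX": ""})
        out = collapse_probes(per_probe, ann)
        assert list(out.index) == ["G1"]
        assert out.loc["G1", "probe"] == "pA"

    @pytest.mark.parametrize(
        "log2fc,adj_p,kept",
        [(1.3, 0.005, True), (-1.5, 0.009, True), (1.19, 0.001, False), (1.3, 0.01, False)],
    )
    def test_threshold_arithmetic(self, log2fc, adj_p, kept):
        records = pd.DataFrame({"log2fc": [log2fc], "adj_p": [adj_p]}, index=["G"])
        genes = filter_degs(records)
        assert ("G" in genes) is kept
        if kept:
            assert genes.direction["G"] == ("up" if log2fc > 0 else "down")


def test_planted_genes_recovered_from_synthetic_dataset(small_study):
    """Genes planted at six noise standard deviations must be called DEGs."""
    from crosskey.deg import preprocess

    (values, groups, annotation) = small_study.datasets[("P1", 1)]
    ds = preprocess(values, groups, name="P1_d1")
    table, genes = deg_table(ds, annotation)
    planted = set(small_study.truth.de_genes)
    assert planted <= genes.genes
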