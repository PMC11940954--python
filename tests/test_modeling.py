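"""ANOVA screening, oversampling, standardization, cross-validated metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from infantmotion.modeling import (
    MODEL_NAMES,
    _fold_metrics,
    anova_f_oneway,
    anova_filter,
    crossval_evaluate,
    oversample_minority,
    run_pipeline,
    standardize,
)


def _table(X: np.ndarray, labels: list[str], names=None) -> pd.DataFrame:
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "label", labels)
    return df


def _gaussian_table(rng, n_per_class=30, n_features=12, shift=0.0):
    X = rng.normal(size=(2 * n_per_class, n_features))
    X[n_per_class:, : n_features // 2] += shift
    labels = ["typical"] * n_per_class + ["delayed"] * n_per_class
    return _table(X, labels)


class TestAnova:
    def test_identical_groups_not_retained(self, rng):
        X = np.tile(rng.normal(size=(5, 1)), (2, 1))
        table = _table(X, ["typical"] * 5 + ["delayed"] * 5)
        assert anova_filter(table, alpha=0.05) == []

    def test_zero_within_variance_retained(self):
        X = np.array([[1.0], [1.0], [1.0], [2.0], [2.0], [2.0]])
        table = _table(X, ["typical"] * 3 + ["delayed"] * 3)
        F, p = anova_f_oneway(X, table["label"].to_numpy())
        assert np.isinf(F[0]) and p[0] == 0.0
        assert anova_filter(table) == ["f0"]

    def test_f_equals_squared_t(self, rng):
        X = rng.normal(size=(40, 50))
        groups = np.array(["typical"] * 25 + ["delayed"] * 15)
        F, p = anova_f_oneway(X, groups)
        t, pt = stats.ttest_ind(X[groups == "typical"], X[groups == "delayed"], axis=0)
        assert np.allclose(F, t**2, rtol=1e-9)
        assert np.allclose(p, pt, rtol=1e-9)

    def test_selection_invariant_to_row_order_and_scaling(self, rng):
        table = _gaussian_table(rng, shift=1.5)
        base = anova_filter(table)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert anova_filter(shuffled) == base
        scaled = table.copy()
        feats = [c for c in table.columns if c != "label"]
        scaled[feats] = scaled[feats] * 1e4 + 17.0
        assert anova_filter(scaled) == base

    def test_single_group_rejected(self, rng):
        table = _table(rng.normal(size=(6, 3)), ["typical"] * 6)
        with pytest.raises(ValueError):
            anova_filter(table)

    def test_bh_adjustment_is_no_more_permissive(self, rng):
        table = _gaussian_table(rng, shift=0.8)
        assert set(anova_filter(table, adjust="bh")) <= set(anova_filter(table))


class TestOversampling:
    def test_exact_triple_replication(self, rng):
        X = rng.normal(size=(83 + 26, 4))
        table = _table(X, ["typical"] * 83 + ["delayed"] * 26)
        out = oversample_minority(table, 78, seed=0)
        counts = out["label"].value_counts()
        assert counts["delayed"] == 78
        assert counts["typical"] == 83
        # every original minority row appears exactly 3 times
        minority = out[out["label"] == "delayed"]
        assert minority.groupby(list(minority.columns)).size().eq(3).all()

    def test_target_equal_to_minority_is_noop(self, rng):
        table = _gaussian_table(rng, n_per_class=10)
        out = oversample_minority(table, 10, seed=0)
        pd.testing.assert_frame_equal(out, table)

    def test_remainder_draw_is_deterministic(self, rng):
        X = rng.normal(size=(20 + 5, 3))
        table = _table(X, ["typical"] * 20 + ["delayed"] * 5)
        a = oversample_minority(table, 12, seed=7)
        b = oversample_minority(table, 12, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert (a["label"] == "delayed").sum() == 12

    def test_target_below_minority_rejected(self, rng):
        table = _gaussian_table(rng, n_per_class=10)
        with pytest.raises(ValueError):
            oversample_minority(table, 5, seed=0)


class TestStandardize:
    def test_three_point_column(self):
        table = _table(np.array([[1.0], [2.0], [3.0]]), ["typical", "typical", "delayed"])
        out, _ = standardize(table)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        assert np.allclose(out["f0"], expected)
        assert out["f0"].iloc[2] == pytest.approx(1.2247, abs=1e-4)

    def test_constant_column_maps_to_zero(self):
        table = _table(np.full((4, 1), 9.0), ["typical"] * 2 + ["delayed"] * 2)
        out, _ = standardize(table)
        assert (out["f0"] == 0.0).all()

    def test_idempotent(self, rng):
        table = _gaussian_table(rng)
        once, _ = standardize(table)
        twice, _ = standardize(once)
        feats = [c for c in table.columns if c != "label"]
        assert np.allclose(once[feats], twice[feats], atol=1e-12)


class TestCrossval:
    def test_separable_table_scores_high(self, rng):
        table = _gaussian_table(rng, n_per_class=30, shift=6.0)
        report = crossval_evaluate(table, "random_forest", n_folds=5, seed=0)
        for metric, value in report.weighted_avg.items():
            assert value >= 0.95, metric

    def test_fold_metrics_f1_identity(self):
        y_true = np.array([0, 0, 0, 0, 1, 1, 1])
        y_pred = np.array([0, 0, 1, 0, 1, 0, 1])
        m = _fold_metrics(y_true, y_pred, score_pos=y_pred.astype(float))
        per_class = []
        for cls in (0, 1):
            tp = np.sum((y_true == cls) & (y_pred == cls))
            prec = tp / max(np.sum(y_pred == cls), 1)
            rec = tp / np.sum(y_true == cls)
            f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
            per_class.append((f1, np.sum(y_true == cls)))
        weighted = sum(f * n for f, n in per_class) / len(y_true)
        assert m["f1"] == pytest.approx(weighted, abs=1e-12)

    def test_deterministic_under_seed(self, rng):
        table = _gaussian_table(rng, shift=2.0)
        a = crossval_evaluate(table, "xgboost", n_folds=4, seed=3)
        b = crossval_evaluate(table, "xgboost", n_folds=4, seed=3)
        assert a.weighted_avg == b.weighted_avg
        assert a.per_fold == b.per_fold

    def test_unknown_model_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown model"):
            crossval_evaluate(_gaussian_table(rng), "perceptron", seed=0)

    def test_balanced_classes_weighted_equals_macro(self, rng):
        table = _gaussian_table(rng, n_per_class=25, shift=1.0)
        report = crossval_evaluate(table, "logistic_regression", n_folds=5, seed=1)
        for metric in ("accuracy", "f1"):
            assert report.weighted_avg[metric] == pytest.approx(
                report.macro_avg[metric], abs=1e-12
            )


class TestPipeline:
    def test_emits_one_report_per_model(self, rng):
        table = _gaussian_table(rng, n_per_class=20, shift=3.0)
        result = run_pipeline(table, n_folds=4, seed=0)
        assert set(result["reports"]) == set(MODEL_NAMES)
        assert result["n_features_total"] == 12
        assert 0 < result["n_features_selected"] <= 12

    def test_leakage_safe_mode_runs(self, rng):
        table = _gaussian_table(rng, n_per_class=20, shift=3.0)
        result = run_pipeline(
            table, models=("random_forest",), n_folds=4, seed=0, leakage_safe=True
        )
        assert result["leakage_safe"] is True
        assert result["reports"]["random_forest"].weighted_avg["f1"] > 0.9
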