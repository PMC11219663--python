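"""Metrics, ROC/AUC, Youden cutoff, k-fold CV, importances, group tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icpforecast.evalstats import (
    MetricsReport,
    group_compare,
    importance,
    kfold_cv,
    roc_auc,
    threshold_metrics,
    youden_cutoff,
)
from icpforecast.rf_pipeline import RFConfig, fit_rf

from test_rf_pipeline import synth_table


def auc_paircount(scores, labels):
    """O(n^2) Mann-Whitney pair oracle with ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_null_scores_near_half(self, rng):
        labels = rng.integers(0, 2, size=2000)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, size=2000)
        _, auc = roc_auc(rng.random(2000), labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_matches_paircount_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 80))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            # discretized scores force ties
            scores = np.round(rng.random(n), 1)
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_paircount(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, size=300)
        labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(300), 2)
        assert roc_auc(scores, labels)[1] == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_points_consistent_with_strict_threshold_rule(self, rng):
        scores = np.round(rng.random(50), 1)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        points, _ = roc_auc(scores, labels)
        for _, row in points.iloc[:10].iterrows():
            m = threshold_metrics(scores, labels, row.threshold)
            assert m.sensitivity == pytest.approx(row.tpr)
            assert 1 - m.specificity == pytest.approx(row.fpr)


class TestYouden:
    def test_printed_formula(self):
        # J = sensitivity + specificity - 1
        assert 0.91 + 0.56 - 1 == pytest.approx(0.47)

    def test_perfect_classifier_j_is_one(self):
        cutoff, j = youden_cutoff([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert j == pytest.approx(1.0)
        m = threshold_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], cutoff)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            scores = np.round(rng.random(60), 1)
            labels = rng.integers(0, 2, size=60)
            labels[:2] = [0, 1]
            cutoff, j = youden_cutoff(scores, labels)
            candidates = np.r_[np.unique(scores), scores.min() - 1]
            best = max(
                threshold_metrics(scores, labels, c).sensitivity
                + threshold_metrics(scores, labels, c).specificity
                - 1
                for c in candidates
            )
            assert j == pytest.approx(best, abs=1e-12)
            m = threshold_metrics(scores, labels, cutoff)
            assert m.sensitivity + m.specificity - 1 == pytest.approx(j)

    def test_ties_take_lowest_cutoff(self):
        cutoff, _ = youden_cutoff([0.6, 0.6, 0.4, 0.4], [1, 1, 0, 0])
        assert cutoff == pytest.approx(0.4)


class TestThresholdMetrics:
    def test_worked_confusion_table(self):
        m = MetricsReport(tp=10, fn=1, tn=5, fp=4)
        assert m.sensitivity == pytest.approx(0.909, abs=1e-3)
        assert m.specificity == pytest.approx(0.556, abs=1e-3)
        assert m.accuracy == pytest.approx(0.75)
        assert m.recall == m.sensitivity

    def test_all_predicted_positive(self):
        m = threshold_metrics([0.9, 0.8, 0.7], [1, 0, 1], cutoff=0.0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_f1_harmonic_mean_oracle(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            m = MetricsReport(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
            p = tp / (tp + fp) if tp + fp else np.nan
            r = tp / (tp + fn) if tp + fn else np.nan
            expected = (
                0.0
                if not np.isfinite(p) or not np.isfinite(r) or p + r == 0
                else 2 * p * r / (p + r)
            )
            assert m.f1 == pytest.approx(expected)

    def test_strict_inequality_at_cutoff(self):
        m = threshold_metrics([0.5, 0.6], [1, 1], cutoff=0.5)
        assert m.tp == 1 and m.fn == 1  # score == cutoff is negative


class TestKfoldCv:
    def test_fold_partition_and_sizes(self):
        df = synth_table(69, seed=21)
        report = kfold_cv(df, "ih", RFConfig(seed=21, mtry_grid=(2,), min_node_grid=(1,)), k=5, seed=3)
        assert report.k == 5
        sizes = sorted(m.tp + m.fp + m.tn + m.fn for m in report.fold_metrics)
        assert sizes == [13, 14, 14, 14, 14]

    def test_planted_effect_cv_auc(self):
        df = synth_table(120, seed=22, effect=1.5)
        report = kfold_cv(df, "ih", RFConfig(seed=22, mtry_grid=(2,), min_node_grid=(1,)), k=5, seed=4)
        s = report.summary()
        assert s.loc["auc", "mean"] > 0.7
        assert (s.loc[:, "mean"] >= 0).all()

    def test_metric_means_within_fold_range(self):
        df = synth_table(100, seed=23)
        report = kfold_cv(df, "ih", RFConfig(seed=23, mtry_grid=(2,), min_node_grid=(1,)), k=5, seed=5)
        s = report.summary()
        per_fold = pd.DataFrame([m.to_dict() for m in report.fold_metrics])
        for metric in ("accuracy", "auc"):
            assert per_fold[metric].min() - 1e-12 <= s.loc[metric, "mean"]
            assert s.loc[metric, "mean"] <= per_fold[metric].max() + 1e-12

    def test_small_class_rejected(self):
        df = synth_table(30, seed=24)
        df["ih"] = np.r_[np.ones(3, int), np.zeros(27, int)]
        with pytest.raises(ValueError):
            kfold_cv(df, "ih", RFConfig(), k=5, seed=1)


class TestImportance:
    def test_planted_signal_ranks_first(self):
        hits = 0
        for s in range(10):
            df = synth_table(200, p_noise=4, p_info=1, effect=1.5, seed=200 + s)
            model = fit_rf(
                df, list(df.columns[:-1]), RFConfig(seed=s, mtry_grid=(2,), min_node_grid=(1,)),
                task="ih",
            )
            imp = importance(model, df)
            if imp.iloc[0].feature == "info0":
                hits += 1
            assert (imp.mdg >= 0).all()
        assert hits >= 9

    def test_noise_feature_mda_near_zero(self):
        mdas = []
        for s in range(10):
            df = synth_table(200, p_noise=3, p_info=1, effect=1.5, seed=300 + s)
            model = fit_rf(
                df, list(df.columns[:-1]), RFConfig(seed=s, mtry_grid=(2,), min_node_grid=(1,)),
                task="ih",
            )
            imp = importance(model, df).set_index("feature")
            mdas.append(imp.loc["noise0", "mda"])
        se = np.std(mdas, ddof=1) / np.sqrt(len(mdas))
        assert abs(np.mean(mdas)) < 2 * se + 0.01


class TestGroupCompare:
    def test_normal_groups_use_t_test_with_power(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            a = rng.normal(1, 1, 30)
            b = rng.normal(0, 1, 30)
            df = pd.DataFrame({"v": np.r_[a, b], "ih": np.r_[np.ones(30, int), np.zeros(30, int)]})
            row = group_compare(df, "ih", variables=["v"]).iloc[0]
            if row.test == "t" and row.p < 0.01:
                hits += 1
        assert hits >= 80  # t test chosen and significant in most runs

    def test_identical_groups_p_uniform(self, rng):
        ps = []
        for _ in range(200):
            v = rng.normal(size=40)
            df = pd.DataFrame({"v": v, "ih": np.r_[np.ones(20, int), np.zeros(20, int)]})
            ps.append(group_compare(df, "ih", variables=["v"]).iloc[0].p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_binary_variable_routed_to_chi_square(self, rng):
        df = pd.DataFrame(
            {"sex": rng.integers(0, 2, 80), "ih": rng.integers(0, 2, 80)}
        )
        df.loc[:1, "ih"] = [0, 1]
        row = group_compare(df, "ih", variables=["sex"]).iloc[0]
        assert row.test == "chi-square"

    def test_skewed_variable_routed_to_mannwhitney(self, rng):
        v = rng.exponential(size=100) ** 2
        df = pd.DataFrame({"v": v, "ih": rng.integers(0, 2, 100)})
        df.loc[:1, "ih"] = [0, 1]
        row = group_compare(df, "ih", variables=["v"]).iloc[0]
        assert row.test == "mann-whitney"

    def test_zero_variance_skipped(self):
        df = pd.DataFrame({"v": np.ones(20), "ih": np.r_[np.ones(10, int), np.zeros(10, int)]})
        row = group_compare(df, "ih", variables=["v"]).iloc[0]
        assert row.test == "skipped"

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"v": np.ones(10), "ih": np.ones(10, int)})
        with pytest.raises(ValueError):
            group_compare(df, "ih", variables=["v"])
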