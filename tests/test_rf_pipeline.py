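"""Stratified split, RFE-CV, VIF, forest fitting and prediction."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from icpforecast.rf_pipeline import (
    RFConfig,
    SplitSpec,
    fit_rf,
    load_model,
    predict_proba,
    rfe_cv,
    save_model,
    stratified_split,
    vif,
)

CFG = RFConfig(seed=0)


def synth_table(n=200, p_noise=7, p_info=3, effect=1.2, seed=0, task="ih"):
    """Planted-feature table: p_info informative columns, p_noise pure noise."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    cols = {}
    for j in range(p_info):
        cols[f"info{j}"] = rng.normal(size=n) + effect * y
    for j in range(p_noise):
        cols[f"noise{j}"] = rng.normal(size=n)
    df = pd.DataFrame(cols)
    df[task] = y
    return df


class TestStratifiedSplit:
    def test_proportionality(self):
        df = synth_table(100, seed=3)
        df["ih"] = np.r_[np.ones(60, int), np.zeros(40, int)]
        train, test = stratified_split(df, SplitSpec(train_fraction=0.7, seed=1))
        assert len(train) == 70 and len(test) == 30
        assert abs(int(train.ih.sum()) - 42) <= 1

    def test_deterministic(self):
        df = synth_table(80, seed=4)
        a1, b1 = stratified_split(df, SplitSpec(seed=9))
        a2, b2 = stratified_split(df, SplitSpec(seed=9))
        assert list(a1.index) == list(a2.index) and list(b1.index) == list(b2.index)

    def test_disjoint_exhaustive(self):
        df = synth_table(101, seed=5)
        train, test = stratified_split(df, SplitSpec(seed=2))
        assert set(train.index) | set(test.index) == set(df.index)
        assert not set(train.index) & set(test.index)

    def test_single_class_rejected(self):
        df = synth_table(40, seed=6)
        df["ih"] = 1
        with pytest.raises(ValueError):
            stratified_split(df, SplitSpec())

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


class TestRfeCv:
    def test_single_candidate_returned(self):
        df = synth_table(60, p_noise=0, p_info=1, seed=7)
        assert rfe_cv(df, "ih", CFG, feature_cols=["info0"]) == ["info0"]

    def test_deterministic(self):
        df = synth_table(120, seed=8)
        cols = [c for c in df.columns if c != "ih"]
        assert rfe_cv(df, "ih", CFG, feature_cols=cols) == rfe_cv(
            df, "ih", CFG, feature_cols=cols
        )

    def test_informative_features_recovered(self):
        # single run; the acceptance suite repeats this over 20 seeds
        df = synth_table(300, seed=9)
        sel = rfe_cv(df, "ih", RFConfig(seed=9), feature_cols=list(df.columns[:-1]))
        assert {"info0", "info1", "info2"} <= set(sel)

    def test_collinear_duplicate_changes_little(self):
        df = synth_table(200, p_noise=2, p_info=2, seed=10)
        df["dup"] = df["info0"]
        cols = ["info0", "info1", "noise0", "noise1", "dup"]
        from icpforecast.rf_pipeline import _impute, _inner_cv_auc

        y = df["ih"].to_numpy()
        auc_with = _inner_cv_auc(df[cols].to_numpy(), y, CFG, "sqrt", 1, seed=1)
        auc_without = _inner_cv_auc(df[cols[:-1]].to_numpy(), y, CFG, "sqrt", 1, seed=1)
        assert abs(auc_with - auc_without) < 0.05

    def test_too_few_rows_rejected(self):
        df = synth_table(8, seed=11)
        with pytest.raises(ValueError):
            rfe_cv(df, "ih", CFG, feature_cols=list(df.columns[:-1]))


class TestVif:
    def test_orthogonal_predictors_near_one(self, rng):
        n = 500
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        report = vif(df, ["a", "b", "c"])
        assert (report.values < 1.1).all()
        assert report.flagged == []

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_two_predictor_closed_form(self, rho, rng):
        n = 500
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y})
        expected = 1.0 / (1.0 - rho**2)
        report = vif(df, ["x", "y"])
        assert report.values["x"] == pytest.approx(expected, abs=0.2 + 0.3 * expected * 0.1)
        assert report.values["y"] == pytest.approx(expected, abs=0.2 + 0.3 * expected * 0.1)

    def test_duplicated_column_is_infinite(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": x.copy(), "z": rng.normal(size=100)})
        report = vif(df, ["x", "y", "z"])
        assert np.isinf(report.values["x"]) and np.isinf(report.values["y"])

    def test_more_features_than_rows_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            vif(df, list("abcd"))


class TestFitPredict:
    def test_planted_effect_oob_auc(self):
        from icpforecast.evalstats import roc_auc

        df = synth_table(200, seed=12)
        model = fit_rf(df, ["info0", "info1", "info2"], RFConfig(seed=12), task="ih")
        pos = list(model.forest.classes_).index(1)
        oob = model.forest.oob_decision_function_[:, pos]
        ok = np.isfinite(oob)
        assert roc_auc(oob[ok], df["ih"].to_numpy()[ok])[1] > 0.7

    def test_permuted_labels_null_auc(self):
        from icpforecast.evalstats import roc_auc

        rng = np.random.default_rng(13)
        aucs = []
        for s in range(10):
            df = synth_table(150, seed=100 + s)
            df["ih"] = rng.permutation(df["ih"].to_numpy())
            if df["ih"].sum() in (0, len(df)):
                continue
            model = fit_rf(df, ["info0", "info1"], RFConfig(seed=s), task="ih")
            pos = list(model.forest.classes_).index(1)
            oob = model.forest.oob_decision_function_[:, pos]
            ok = np.isfinite(oob)
            aucs.append(roc_auc(oob[ok], df["ih"].to_numpy()[ok])[1])
        assert 0.35 < np.mean(aucs) < 0.65

    def test_forest_size_stability(self):
        from icpforecast.evalstats import roc_auc

        df = synth_table(200, seed=14)
        aucs = {}
        for nt in (100, 500, 1000):
            model = fit_rf(
                df,
                ["info0", "info1", "info2"],
                RFConfig(seed=14, n_trees=nt, mtry_grid=(2,), min_node_grid=(1,)),
                task="ih",
            )
            pos = list(model.forest.classes_).index(1)
            oob = model.forest.oob_decision_function_[:, pos]
            ok = np.isfinite(oob)
            aucs[nt] = roc_auc(oob[ok], df["ih"].to_numpy()[ok])[1]
        assert abs(aucs[500] - aucs[1000]) < 0.03
        assert abs(aucs[100] - aucs[500]) < 0.05

    def test_constant_feature_dropped_with_warning(self):
        df = synth_table(100, seed=15)
        df["flat"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            model = fit_rf(df, ["info0", "flat"], CFG, task="ih")
        assert model.selected_features == ["info0"]

    def test_cutoff_in_unit_interval(self):
        df = synth_table(120, seed=16)
        model = fit_rf(df, ["info0", "info1"], CFG, task="ih")
        assert 0.0 <= model.cutoff <= 1.0

    def test_predict_proba_bounds_and_consistency(self):
        df = synth_table(120, seed=17)
        model = fit_rf(df, ["info0", "info1"], CFG, task="ih")
        p = predict_proba(model, df)
        assert (p >= 0).all() and (p <= 1).all()
        np.testing.assert_array_equal(p, predict_proba(model, df))
        # strong positive rows score high
        strong = df[df.ih == 1].nlargest(5, "info0")
        assert predict_proba(model, strong).mean() > 0.5

    def test_missing_feature_column_rejected(self):
        df = synth_table(120, seed=18)
        model = fit_rf(df, ["info0", "info1"], CFG, task="ih")
        with pytest.raises(KeyError):
            predict_proba(model, df.drop(columns=["info1"]))

    def test_missing_values_imputed_by_train_median(self):
        df = synth_table(120, seed=19)
        model = fit_rf(df, ["info0", "info1"], CFG, task="ih")
        rows = df.head(3).copy()
        rows.loc[rows.index, "info0"] = np.nan
        imputed = rows.fillna(model.train_medians)
        np.testing.assert_array_equal(
            predict_proba(model, rows), predict_proba(model, imputed)
        )

    def test_model_roundtrip(self, tmp_path):
        df = synth_table(120, seed=20)
        model = fit_rf(df, ["info0", "info1"], CFG, task="ih")
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.selected_features == model.selected_features
        assert loaded.cutoff == model.cutoff
        np.testing.assert_array_equal(
            predict_proba(loaded, df), predict_proba(model, df)
        )
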