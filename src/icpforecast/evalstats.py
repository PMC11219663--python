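"""Evaluation statistics: ROC/AUC, Youden cutoff, threshold metrics,
fivefold cross-validation, forest feature importances, and cohort group
comparisons.

All threshold logic uses the strict convention ``predicted positive iff
score > cutoff``; ROC points, Youden scan and confusion metrics share it,
so a cutoff chosen here reproduces exactly the metrics reported at it.
The trapezoidal AUC over all thresholds equals the Mann-Whitney pair
statistic U / (n1 * n0) with ties counted one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricsReport",
    "CVReport",
    "roc_auc",
    "youden_cutoff",
    "threshold_metrics",
    "kfold_cv",
    "importance",
    "group_compare",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "recall", "f1", "auc")


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived threshold metrics (plus AUC)."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float = float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / max(self.tp + self.tn + self.fp + self.fn, 1)

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def recall(self) -> float:
        return self.sensitivity

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if not np.isfinite(p) or not np.isfinite(r) or (p + r) == 0:
            return 0.0
        return 2 * p * r / (p + r)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in METRIC_NAMES}
        d.update(tp=self.tp, fp=self.fp, tn=self.tn, fn=self.fn)
        return d


@dataclass
class CVReport:
    k: int
    fold_metrics: list[MetricsReport] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = pd.DataFrame([m.to_dict() for m in self.fold_metrics])[list(METRIC_NAMES)]
        return pd.DataFrame({"mean": rows.mean(), "sd": rows.std(ddof=1)})


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"need both classes present (0 and 1), got {classes}")
    return y


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points (strict ``>`` convention) and trapezoidal AUC.

    Thresholds are the distinct scores in descending order plus ``-inf``
    (the all-positive operating point); at threshold t, a row is predicted
    positive iff its score is strictly greater than t.
    """
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    pos = np.sort(scores[y == 1])
    neg = np.sort(scores[y == 0])
    n1, n0 = len(pos), len(neg)
    thr = np.concatenate([np.unique(scores)[::-1], [-np.inf]])
    # count of scores strictly greater than each threshold
    tpr = (n1 - np.searchsorted(pos, thr, side="right")) / n1
    fpr = (n0 - np.searchsorted(neg, thr, side="right")) / n0
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def youden_cutoff(scores, labels) -> tuple[float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1 (ties: lowest).

    The scan covers every achievable operating point under the strict
    ``score > cutoff`` rule; with probability scores the returned cutoff is
    clipped into [0, 1].
    """
    points, _ = roc_auc(scores, labels)
    thr = points["threshold"].to_numpy().copy()
    # the all-positive endpoint is realized by any cutoff below the lowest
    # score; use min - 1 so `score > cutoff` holds for every row exactly
    thr[~np.isfinite(thr)] = float(np.min(scores)) - 1.0
    j = points["tpr"].to_numpy() - points["fpr"].to_numpy()
    best = j.max()
    cutoff = float(thr[j >= best - 1e-12].min())
    return cutoff, float(best)


def threshold_metrics(scores, labels, cutoff: float, auc: float | None = None) -> MetricsReport:
    """Confusion counts and metrics at ``prediction = score > cutoff``."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = scores > cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    if auc is None:
        auc = roc_auc(scores, y)[1] if len(np.unique(y)) == 2 else float("nan")
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, auc=float(auc))


def kfold_cv(
    table: pd.DataFrame,
    task: str,
    config,
    k: int = 5,
    seed: int = 0,
    feature_cols: list[str] | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation of the *entire* pipeline.

    Inside each training split the full recipe is re-run from scratch —
    median imputation, RFE-CV feature selection, the hyperparameter grid
    search, and the Youden cutoff from training OOB probabilities — and the
    held-out fold is scored at that cutoff.
    """
    from dataclasses import replace as dc_replace

    from sklearn.model_selection import StratifiedKFold

    from . import rf_pipeline

    y = _check_binary(table[task].to_numpy())
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"each class needs >= k={k} members, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    report = CVReport(k=k)
    for i, (tr, te) in enumerate(skf.split(table, y)):
        train, test = table.iloc[tr], table.iloc[te]
        fold_config = dc_replace(config, seed=config.seed + 1000 * (i + 1))
        selected = rf_pipeline.rfe_cv(train, task, fold_config, feature_cols=feature_cols)
        model = rf_pipeline.fit_rf(train, selected, fold_config, task=task)
        scores = rf_pipeline.predict_proba(model, test)
        y_te = test[task].to_numpy(dtype=int)
        auc = roc_auc(scores, y_te)[1] if len(np.unique(y_te)) == 2 else float("nan")
        report.fold_metrics.append(threshold_metrics(scores, y_te, model.cutoff, auc=auc))
    return report


def importance(model, train: pd.DataFrame) -> pd.DataFrame:
    """Mean Decrease Accuracy and Mean Decrease Gini per selected feature.

    MDA permutes each feature over each tree's out-of-bag rows and averages
    the accuracy drop; MDG averages the (unnormalized) Gini impurity
    decrease attributed to the feature across trees.  Ordered by MDA.
    """
    from . import rf_pipeline

    X = rf_pipeline._impute(train[model.selected_features], model.train_medians)
    y = train[model.task].to_numpy(dtype=int)
    mda = rf_pipeline.oob_permutation_importance(model.forest, X, y, seed=0)
    mdg = np.mean(
        [t.tree_.compute_feature_importances(normalize=False) for t in model.forest.estimators_],
        axis=0,
    )
    out = pd.DataFrame(
        {"feature": model.selected_features, "mda": mda, "mdg": mdg}
    ).sort_values("mda", ascending=False, ignore_index=True)
    return out


def _is_binary(x: pd.Series) -> bool:
    vals = set(pd.unique(x.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def group_compare(
    table: pd.DataFrame,
    outcome: str = "ih",
    variables: list[str] | None = None,
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Cohort characteristics table: per-variable two-group comparison.

    Continuous variables use the t test when Shapiro-Wilk accepts normality
    in *both* groups (at alpha 0.05), else the Mann-Whitney U test;
    binary/categorical variables use the chi-square test.  Normal variables
    are summarized as mean (SD), non-normal as median [IQR].
    """
    from .features import FEATURE_COLUMNS

    if variables is None:
        variables = [c for c in FEATURE_COLUMNS if c in table.columns]
    g1 = table[table[outcome] == 1]
    g0 = table[table[outcome] == 0]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both outcome groups must be nonempty")
    rows = []
    for var in variables:
        a = g1[var].dropna().to_numpy(dtype=float)
        b = g0[var].dropna().to_numpy(dtype=float)
        row = {"variable": var, "n_pos": len(a), "n_neg": len(b)}
        if len(a) == 0 or len(b) == 0 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            row.update(test="skipped", statistic=np.nan, p=np.nan,
                       summary_pos="-", summary_neg="-", note="zero variance or empty")
            rows.append(row)
            continue
        if _is_binary(table[var]):
            tab = pd.crosstab(table[outcome], table[var])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                chi2, p, _, _ = stats.chi2_contingency(tab)
            row.update(
                test="chi-square", statistic=float(chi2), p=float(p),
                summary_pos=f"{int(a.sum())} ({100 * a.mean():.1f}%)",
                summary_neg=f"{int(b.sum())} ({100 * b.mean():.1f}%)",
            )
        else:
            normal = (
                len(a) >= 3
                and len(b) >= 3
                and np.ptp(a) > 0
                and np.ptp(b) > 0
                and stats.shapiro(a).pvalue > alpha_normality
                and stats.shapiro(b).pvalue > alpha_normality
            )
            if normal:
                t, p = stats.ttest_ind(a, b)
                row.update(
                    test="t", statistic=float(t), p=float(p),
                    summary_pos=f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                    summary_neg=f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
                )
            else:
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                qa = np.percentile(a, [25, 50, 75])
                qb = np.percentile(b, [25, 50, 75])
                row.update(
                    test="mann-whitney", statistic=float(u), p=float(p),
                    summary_pos=f"{qa[1]:.2f} [{qa[0]:.2f}, {qa[2]:.2f}]",
                    summary_neg=f"{qb[1]:.2f} [{qb[0]:.2f}, {qb[2]:.2f}]",
                )
        rows.append(row)
    return pd.DataFrame(rows)
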