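"""Random-forest modeling workflow for the IH and SIH prediction tasks.

The workflow mirrors a small-cohort clinical modeling recipe: a stratified
70/30 split, recursive feature elimination with inner cross-validation
(RFE-CV) to pick the feature subset, a hyperparameter grid search scored by
inner-CV AUC, a multicollinearity screen (variance inflation factors), a
final forest refit with out-of-bag (OOB) scoring, and a classification
cutoff chosen by Youden's index on the *training* OOB probabilities so the
test partition never influences any fitted quantity.

RFE drops one feature per iteration, ranked by permutation importance
measured on the held-out inner folds (the "Mean Decrease Accuracy"
criterion, computed out-of-sample); the retained set size maximizes mean
inner-CV AUC, with ties resolved toward the smaller set.  Missing feature
values are imputed by training-set medians throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from .evalstats import roc_auc, youden_cutoff
from .features import FEATURE_COLUMNS

__all__ = [
    "SplitSpec",
    "RFConfig",
    "FittedModel",
    "VIFReport",
    "stratified_split",
    "rfe_cv",
    "vif",
    "fit_rf",
    "predict_proba",
    "oob_permutation_importance",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    stratify_on: str = "ih"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class RFConfig:
    """Forest and search settings.

    ``mtry_grid`` (features per split) defaults to {1, 2, 3, floor(sqrt(p))+1}
    clipped to the candidate count; ``min_node_grid`` (minimum leaf size) to
    {1, 5, 10}.  Grid winners are chosen by mean inner-CV AUC.  The default
    forest size (100 trees) keeps the nested RFE-CV / grid-search / k-fold
    workflow desk-scale; tests assert the OOB AUC is insensitive to much
    larger forests.
    """

    n_trees: int = 100
    mtry_grid: tuple[int, ...] | None = None
    min_node_grid: tuple[int, ...] = (1, 5, 10)
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 100:
            raise ValueError("n_trees must be >= 100")
        if self.mtry_grid is not None and len(self.mtry_grid) == 0:
            raise ValueError("mtry_grid must be nonempty")
        if len(self.min_node_grid) == 0:
            raise ValueError("min_node_grid must be nonempty")


@dataclass
class FittedModel:
    task: str
    selected_features: list[str]
    hyperparams: dict
    forest: RandomForestClassifier
    cutoff: float
    train_medians: pd.Series

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must be in [0, 1]")


@dataclass
class VIFReport:
    values: pd.Series
    flag_threshold: float = 5.0

    @property
    def flagged(self) -> list[str]:
        return [f for f, v in self.values.items() if v > self.flag_threshold]


def infer_feature_columns(table: pd.DataFrame) -> list[str]:
    known = [c for c in FEATURE_COLUMNS if c in table.columns]
    if known:
        return known
    return [
        c
        for c in table.columns
        if c not in ("patient_id", "ih", "sih") and pd.api.types.is_numeric_dtype(table[c])
    ]


def _impute(X: pd.DataFrame, medians: pd.Series) -> np.ndarray:
    return X.fillna(medians).to_numpy(dtype=float)


def _forest(config: RFConfig, mtry: int | str = "sqrt", min_node: int = 1, seed: int = 0):
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=mtry,
        min_samples_leaf=min_node,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def stratified_split(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded stratified train/test split preserving outcome balance."""
    y = table[spec.stratify_on]
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError(
            f"both outcome classes need >= 2 members, got {counts.to_dict()}"
        )
    train, test = train_test_split(
        table,
        train_size=spec.train_fraction,
        stratify=y,
        random_state=spec.seed,
        shuffle=True,
    )
    return train, test


def _tree_oob_indices(tree, n_samples: int) -> np.ndarray:
    try:
        from sklearn.ensemble._forest import _generate_unsampled_indices

        # max_samples=None -> bootstrap size equals the training-set size
        return _generate_unsampled_indices(tree.random_state, n_samples, n_samples)
    except (ImportError, TypeError):  # pragma: no cover - mirrors sklearn's draw
        from sklearn.utils import check_random_state

        sampled = check_random_state(tree.random_state).randint(
            0, n_samples, n_samples, dtype=np.int32
        )
        mask = np.ones(n_samples, dtype=bool)
        mask[sampled] = False
        return np.flatnonzero(mask)


def oob_permutation_importance(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Mean Decrease Accuracy: per-tree OOB accuracy drop under permutation.

    For each tree, each feature column of that tree's out-of-bag rows is
    permuted in turn and the accuracy drop relative to the intact OOB
    accuracy is recorded; drops are averaged over trees.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    drops = np.zeros(p)
    n_used = 0
    for tree in forest.estimators_:
        oob = _tree_oob_indices(tree, n)
        if oob.size < 2:
            continue
        Xo, yo = X[oob], y[oob]
        m = oob.size
        perm = rng.permutation(m)
        # one prediction call per tree: rows [base | perm feat 0 | ... | perm feat p-1]
        stack = np.tile(Xo, (p + 1, 1))
        for j in range(p):
            stack[(j + 1) * m : (j + 2) * m, j] = Xo[perm, j]
        pred = tree.predict(stack).reshape(p + 1, m)
        acc = (pred == yo).mean(axis=1)
        drops += acc[0] - acc[1:]
        n_used += 1
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return drops / n_used


def _stratified_folds(y: np.ndarray, n_splits: int, seed: int):
    """Seeded stratified folds; refolds once if a fold comes out
    single-class, then errors."""
    for attempt in (0, 1):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros_like(y), y))
        if all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
            for tr, te in folds
        ):
            return folds
    raise ValueError("degenerate outcome in an inner fold after refolding")


def _inner_cv_eval(
    X: np.ndarray,
    y: np.ndarray,
    config: RFConfig,
    mtry: int | str,
    min_node: int,
    seed: int,
    importance: bool = False,
) -> tuple[float, np.ndarray | None]:
    """Mean held-out AUC over inner folds; optionally also the mean held-out
    permutation-importance (accuracy drop when one feature is shuffled in
    the validation fold, averaged over folds)."""
    folds = _stratified_folds(y, config.inner_cv_folds, seed)
    n, p = X.shape
    rng = np.random.default_rng(seed + 999)
    aucs = []
    drops = np.zeros(p) if importance else None
    for k, (tr, te) in enumerate(folds):
        f = _forest(config, mtry=mtry, min_node=min_node, seed=seed + 100 + k)
        f.fit(X[tr], y[tr])
        pos = list(f.classes_).index(1)
        scores = f.predict_proba(X[te])[:, pos]
        aucs.append(roc_auc(scores, y[te])[1])
        if importance:
            Xt, yt = X[te], y[te]
            m = len(te)
            perm = rng.permutation(m)
            stack = np.tile(Xt, (p + 1, 1))
            for j in range(p):
                stack[(j + 1) * m : (j + 2) * m, j] = Xt[perm, j]
            pred = f.predict(stack).reshape(p + 1, m)
            acc = (pred == yt).mean(axis=1)
            drops += acc[0] - acc[1:]
    if importance:
        drops /= len(folds)
    return float(np.mean(aucs)), drops


def _inner_cv_auc(X, y, config, mtry, min_node, seed) -> float:
    return _inner_cv_eval(X, y, config, mtry, min_node, seed)[0]


def rfe_cv(
    train: pd.DataFrame,
    task: str,
    config: RFConfig,
    feature_cols: list[str] | None = None,
) -> list[str]:
    """Recursive feature elimination with cross-validated set-size choice.

    Starting from all candidates, repeatedly drop the feature with the
    lowest permutation importance (mean held-out accuracy drop across the
    inner folds), recording the mean inner-CV AUC of each set size; return
    the set maximizing that AUC (ties go to the smaller set), ordered by
    descending importance.  Deterministic given ``config.seed``.
    """
    features = list(feature_cols) if feature_cols else infer_feature_columns(train)
    if not features:
        raise ValueError("no candidate features")
    if len(train) < 10:
        raise ValueError("need >= 10 training rows for RFE-CV")
    y = train[task].to_numpy(dtype=int)
    medians = train[features].median()
    history: list[tuple[int, list[str], float]] = []
    current = list(features)
    step = 0
    while current:
        X = _impute(train[current], medians[current])
        auc, imp = _inner_cv_eval(
            X, y, config, "sqrt", 1, seed=config.seed + step,
            importance=len(current) > 1,
        )
        if len(current) == 1:
            history.append((1, list(current), auc))
            break
        order = list(np.argsort(imp)[::-1])  # descending importance
        ranked = [current[i] for i in order]
        history.append((len(current), ranked, auc))
        worst = current[int(np.argmin(imp))]
        current = [c for c in current if c != worst]
        step += 1
    best_auc = max(h[2] for h in history)
    best = min((h for h in history if h[2] >= best_auc - 1e-12), key=lambda h: h[0])
    return best[1]


def vif(table: pd.DataFrame, features: list[str], flag_threshold: float = 5.0) -> VIFReport:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from an ordinary least-squares regression of feature j on
    the other features (with intercept).  Exact collinearity reports +inf.
    """
    if len(features) < 2:
        raise ValueError("VIF needs >= 2 features")
    X = table[features].dropna()
    if len(X) <= len(features):
        raise ValueError("need more rows than features for VIF")
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    exog = sm.add_constant(X.to_numpy(dtype=float))
    values = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, name in enumerate(features, start=1):
            v = variance_inflation_factor(exog, j)
            values[name] = float("inf") if (not np.isfinite(v) or v > 1e12) else float(v)
    return VIFReport(values=pd.Series(values), flag_threshold=flag_threshold)


def fit_rf(
    train: pd.DataFrame, selected: list[str], config: RFConfig, task: str = "ih"
) -> FittedModel:
    """Grid-search, refit, and set the Youden cutoff from training OOB."""
    if not selected:
        raise ValueError("selected feature list is empty")
    selected = list(selected)
    constant = [c for c in selected if train[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"dropping all-constant feature(s): {constant}", stacklevel=2)
        selected = [c for c in selected if c not in constant]
        if not selected:
            raise ValueError("all selected features are constant")
    y = train[task].to_numpy(dtype=int)
    medians = train[selected].median()
    X = _impute(train[selected], medians)
    p = len(selected)
    mtry_grid = config.mtry_grid or tuple(
        sorted({m for m in (1, 2, 3, int(np.sqrt(p)) + 1) if m <= p})
    )
    best = None
    for mtry in mtry_grid:
        for min_node in config.min_node_grid:
            auc = _inner_cv_auc(X, y, config, mtry, min_node, seed=config.seed)
            if best is None or auc > best[0] + 1e-12:
                best = (auc, mtry, min_node)
    _, mtry, min_node = best
    forest = _forest(config, mtry=mtry, min_node=min_node, seed=config.seed)
    forest.set_params(oob_score=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        forest.fit(X, y)
    pos_col = list(forest.classes_).index(1)
    oob = forest.oob_decision_function_[:, pos_col]
    ok = np.isfinite(oob)
    cutoff, _ = youden_cutoff(oob[ok], y[ok])
    return FittedModel(
        task=task,
        selected_features=selected,
        hyperparams={"n_trees": config.n_trees, "mtry": int(mtry), "min_node": int(min_node)},
        forest=forest,
        cutoff=float(np.clip(cutoff, 0.0, 1.0)),
        train_medians=medians,
    )


def predict_proba(model: FittedModel, rows: pd.DataFrame) -> np.ndarray:
    """Positive-class probability (fraction of tree votes) per row."""
    missing = [c for c in model.selected_features if c not in rows.columns]
    if missing:
        raise KeyError(f"rows are missing selected feature(s): {missing}")
    X = _impute(rows[model.selected_features], model.train_medians)
    pos_col = list(model.forest.classes_).index(1)
    return model.forest.predict_proba(X)[:, pos_col]


def save_model(model: FittedModel, path) -> None:
    import joblib

    joblib.dump(
        {
            "task": model.task,
            "selected_features": model.selected_features,
            "hyperparams": model.hyperparams,
            "forest": model.forest,
            "cutoff": model.cutoff,
            "train_medians": model.train_medians,
        },
        path,
    )


def load_model(path) -> FittedModel:
    import joblib

    d = joblib.load(path)
    return FittedModel(**d)
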