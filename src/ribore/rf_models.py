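"""Random-forest regression/classification with CV and permutation importance.

Forests are trained with 100 trees; the per-split feature count (mtry) is
tuned over a coarse grid by 5-fold cross-validation — plain folds for
regression (scored by range-normalised RMSE) and stratified folds for
High/Low classification (scored by AUROC).  Feature importance is measured by
explicit out-of-fit permutation: each original feature's encoded column block
is permuted jointly and the percent increase in MSE (%IncMSE, regression) or
the percentage-point decrease in accuracy (MDA, classification) over the
unpermuted baseline is averaged over repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold

DEFAULT_MTRY_GRID = (1, 11, 21, 31, 41, 51, 61, 71, 81)


@dataclass
class ModelSpec:
    task: str  # "regression" or "classification"
    n_trees: int = 100
    mtry_grid: Sequence[int] = DEFAULT_MTRY_GRID
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class CVReport:
    metric: str  # "NRMSE" or "AUROC"
    fold_values: list[float]
    chosen_mtry: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_values, ddof=1))


def encode_features(
    matrix: pd.DataFrame, schema: Mapping[str, str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-hot encode categoricals; return the model matrix and a group map.

    The group map sends each original feature to its encoded column names so
    permutation importance can be aggregated back to original features.
    Flag columns are dropped; rows with NA must be handled by the caller.
    """
    cols = {}
    groups: dict[str, list[str]] = {}
    for name in matrix.columns:
        kind = schema.get(name, "numeric")
        if kind == "flag":
            continue
        if kind == "categorical":
            levels = sorted(matrix[name].dropna().astype(str).unique())
            names = []
            for lev in levels:
                col = f"{name}={lev}"
                cols[col] = (matrix[name].astype(str) == lev).astype(float)
                names.append(col)
            groups[name] = names
        else:
            cols[name] = pd.to_numeric(matrix[name], errors="coerce")
            groups[name] = [name]
    X = pd.DataFrame(cols, index=matrix.index)
    return X, groups


def drop_or_impute_na(
    X: pd.DataFrame, policy: str = "impute"
) -> tuple[pd.DataFrame, list[str]]:
    """NA policy for the encoded matrix: median-impute or drop rows."""
    na_rows = X.index[X.isna().any(axis=1)].tolist()
    if policy == "drop":
        return X.dropna(), na_rows
    return X.fillna(X.median(numeric_only=True)), na_rows


def nrmse(predicted: np.ndarray, actual: np.ndarray) -> float:
    """RMSE normalised by the range of the observed response."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    rng = actual.max() - actual.min()
    if rng == 0:
        raise ValueError("response has zero range; NRMSE undefined")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)) / rng)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties ½).

    Equivalent to the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _make_forest(spec: ModelSpec, mtry: int, seed: int):
    kwargs = dict(n_estimators=spec.n_trees, max_features=mtry, random_state=seed,
                  n_jobs=1)
    if spec.task == "regression":
        return RandomForestRegressor(**kwargs)
    return RandomForestClassifier(**kwargs)


def _fold_metric(spec: ModelSpec, model, X_te, y_te) -> float:
    if spec.task == "regression":
        return nrmse(model.predict(X_te), y_te)
    pos = list(model.classes_).index(True)
    return auroc(model.predict_proba(X_te)[:, pos], y_te)


def cross_validated_rf(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
) -> tuple[CVReport, object]:
    """Tune mtry on the grid by CV, then refit on all data.

    For classification ``y`` must be boolean (True = High).  Returns the CV
    report at the chosen mtry (per-fold values) and the refitted forest.
    """
    y = np.asarray(y)
    if X.isna().any().any():
        raise ValueError("X contains NA; apply the NA policy first")
    if len(X) < spec.folds * 2:
        raise ValueError(f"need at least {spec.folds * 2} samples")
    if spec.task == "classification":
        if set(np.unique(y)) - {True, False}:
            raise ValueError("classification y must be boolean High/Low")
        splitter = StratifiedKFold(spec.folds, shuffle=True, random_state=spec.seed)
        split_args = (X, y)
        better = max
    else:
        splitter = KFold(spec.folds, shuffle=True, random_state=spec.seed)
        split_args = (X,)
        better = min

    grid = sorted({min(m, X.shape[1]) for m in spec.mtry_grid if m >= 1})
    folds = list(splitter.split(*split_args))
    results = {}
    for mtry in grid:
        vals = []
        for k, (tr, te) in enumerate(folds):
            model = _make_forest(spec, mtry, spec.seed + k)
            model.fit(X.iloc[tr], y[tr])
            vals.append(_fold_metric(spec, model, X.iloc[te], y[te]))
        results[mtry] = vals
    chosen = better(results, key=lambda m: np.mean(results[m]))
    metric = "NRMSE" if spec.task == "regression" else "AUROC"
    report = CVReport(metric=metric, fold_values=results[chosen], chosen_mtry=chosen)
    final = _make_forest(spec, chosen, spec.seed)
    final.fit(X, y)
    return report, final


@dataclass
class ImportanceTable:
    metric: str  # "%IncMSE" or "MDA"
    values: dict[str, float]

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.values.items(), key=lambda kv: -kv[1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": list(self.values), "metric": self.metric,
             "value": list(self.values.values())}
        )


def permutation_importance(
    model,
    X: pd.DataFrame,
    y: np.ndarray,
    groups: Mapping[str, list[str]],
    task: str,
    seed: int = 0,
    n_repeats: int = 5,
) -> ImportanceTable:
    """Permute each original feature's column block; measure the error change.

    Regression reports %IncMSE = 100 · (MSE_perm − MSE_base) / MSE_base;
    classification reports MDA = 100 · (accuracy_base − accuracy_perm)
    (percentage points, robust when the baseline error is zero).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    if task == "regression":
        base = float(np.mean((model.predict(X) - y) ** 2))
    else:
        base = float(np.mean(model.predict(X) == y))
    values = {}
    for feat, cols in groups.items():
        cols = [c for c in cols if c in X.columns]
        if not cols:
            continue
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            perm = rng.permutation(len(X))
            Xp[cols] = X[cols].to_numpy()[perm]
            if task == "regression":
                mse = float(np.mean((model.predict(Xp) - y) ** 2))
                deltas.append(100.0 * (mse - base) / base if base > 0 else 0.0)
            else:
                acc = float(np.mean(model.predict(Xp) == y))
                deltas.append(100.0 * (base - acc))
        values[feat] = float(np.mean(deltas))
    metric = "%IncMSE" if task == "regression" else "MDA"
    return ImportanceTable(metric=metric, values=values)


def per_fold_importance(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: Mapping[str, list[str]],
    spec: ModelSpec,
    mtry: int | None = None,
    n_repeats: int = 5,
) -> list[ImportanceTable]:
    """Out-of-fit permutation importance, one table per CV fold.

    Each fold's forest is trained on the fold's training split and importance
    is measured on the held-out split, so a feature's rank can be compared
    across folds (the stability criterion used for signal recovery).
    """
    y = np.asarray(y)
    if mtry is None:
        mtry = max(1, min(21, X.shape[1]))
    if spec.task == "classification":
        splitter = StratifiedKFold(spec.folds, shuffle=True, random_state=spec.seed)
        folds = splitter.split(X, y)
    else:
        splitter = KFold(spec.folds, shuffle=True, random_state=spec.seed)
        folds = splitter.split(X)
    tables = []
    for k, (tr, te) in enumerate(folds):
        model = _make_forest(spec, min(mtry, X.shape[1]), spec.seed + k)
        model.fit(X.iloc[tr], y[tr])
        tables.append(
            permutation_importance(model, X.iloc[te], y[te], groups, spec.task,
                                   seed=spec.seed + k, n_repeats=n_repeats)
        )
    return tables
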