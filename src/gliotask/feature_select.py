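"""Tabular feature standardization and Lasso-based selection.

The selection procedure: per cross-validation fold, an L1-penalized linear
fit over a log-spaced penalty grid with the penalty chosen on the held-out
part of the fold; nonzero-coefficient features are pooled across folds by
union; the pooled survivors are refit without penalty (OLS) and features with
Wald p > 0.05 are removed. Clinical columns (age, sex) are always retained
when per-task selections are combined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold


@dataclass
class FeatureTable:
    """Feature matrix plus standardization statistics fitted on training rows."""

    matrix: pd.DataFrame
    mean: pd.Series | None = None
    std: pd.Series | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class TaskSelection:
    selected: list[int]
    pooled: list[int]
    per_fold: list[list[int]]
    p_values: dict[int, float]


@dataclass
class SelectionResult:
    sel_idh: TaskSelection
    sel_grade: TaskSelection
    union_indices: list[int]
    clinical_indices: tuple[int, ...] = (99, 100)

    def to_json(self, feature_names: list[str] | None = None) -> str:
        def task_dict(sel: TaskSelection) -> dict:
            return {
                "selected": sel.selected,
                "pooled": sel.pooled,
                "per_fold": sel.per_fold,
                "p_values": {str(k): v for k, v in sel.p_values.items()},
            }

        payload = {
            "idh": task_dict(self.sel_idh),
            "grade": task_dict(self.sel_grade),
            "union_indices": self.union_indices,
        }
        if feature_names is not None:
            payload["union_names"] = [feature_names[i] for i in self.union_indices]
        return json.dumps(payload, indent=2)


def standardize(table: FeatureTable, fit_rows: np.ndarray) -> FeatureTable:
    """Z-score all columns using mean/sd fitted on ``fit_rows`` only.

    Held-out rows are transformed with the training statistics. Zero-variance
    columns map to 0 with a warning. Uses the population (ddof=0) standard
    deviation.
    """
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be nonempty")
    df = table.matrix
    if df.isna().any().any():
        bad = df.columns[df.isna().all()].tolist()
        if bad:
            raise ValueError(f"all-missing columns: {bad}")
        raise ValueError("feature table contains missing values")
    fit = df.iloc[fit_rows] if fit_rows.dtype != bool else df.loc[fit_rows]
    mean = fit.mean(axis=0)
    std = fit.std(axis=0, ddof=0)
    zero_var = std[std == 0].index.tolist()
    if zero_var:
        warnings.warn(f"zero-variance columns mapped to 0: {zero_var}",
                      stacklevel=2)
    safe = std.replace(0.0, 1.0)
    out = (df - mean) / safe
    out[zero_var] = 0.0
    return FeatureTable(matrix=out, mean=mean, std=std)


def _fold_lasso(X_tr, y_tr, X_va, y_va, alpha_grid) -> list[int]:
    """Best-penalty L1 fit on one fold; returns nonzero-coefficient indices."""
    best_alpha, best_score = None, np.inf
    for a in alpha_grid:
        model = Lasso(alpha=a, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X_tr, y_tr)
        score = float(np.mean((model.predict(X_va) - y_va) ** 2))
        if score < best_score:
            best_score, best_alpha = score, a
    model = Lasso(alpha=best_alpha, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X_tr, y_tr)
    return np.flatnonzero(model.coef_ != 0).tolist()


def lasso_select(table: FeatureTable, labels: np.ndarray, n_folds: int = 5,
                 alpha_grid: np.ndarray | None = None, seed: int = 0,
                 p_threshold: float = 0.05,
                 pooling: str = "union") -> TaskSelection:
    """Cross-validated Lasso selection with a p-value filter on survivors."""
    X = table.matrix.to_numpy(dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class; selection undefined")
    if counts.min() < n_folds:
        raise ValueError(
            f"need >= {n_folds} examples per class, got counts {counts.tolist()}")
    if alpha_grid is None:
        alpha_grid = np.logspace(-2.5, 0, 50)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    for tr_idx, va_idx in skf.split(X, y):
        per_fold.append(_fold_lasso(X[tr_idx], y[tr_idx], X[va_idx], y[va_idx],
                                    alpha_grid))
    if pooling == "union":
        pooled = sorted(set().union(*map(set, per_fold)))
    elif pooling == "intersection":
        pooled = sorted(set.intersection(*map(set, per_fold)))
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    p_values: dict[int, float] = {}
    selected: list[int] = []
    if pooled:
        design = sm.add_constant(X[:, pooled])
        fit = sm.OLS(y, design).fit()
        for j, idx in enumerate(pooled):
            p = float(fit.pvalues[j + 1])
            p_values[idx] = p
            if p <= p_threshold:
                selected.append(idx)
    return TaskSelection(selected=selected, pooled=pooled, per_fold=per_fold,
                         p_values=p_values)


def combine_tasks(sel_idh: TaskSelection, sel_grade: TaskSelection,
                  clinical_indices: tuple[int, ...] = (99, 100)) -> SelectionResult:
    """Union of per-task selections, order-stable by column index; clinical
    columns always retained."""
    union = sorted(set(sel_idh.selected) | set(sel_grade.selected)
                   | set(clinical_indices))
    return SelectionResult(sel_idh=sel_idh, sel_grade=sel_grade,
                           union_indices=union, clinical_indices=clinical_indices)
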