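"""Tercile high/low labeling and cross-validated SVM-RBF classification.

Rated images are ranked by one rating term and split into three equally
sized clusters; the lowest and highest thirds become the two classes and the
intermediate third is discarded.  An RBF-kernel support vector machine is
evaluated with stratified 10-fold cross-validation: per fold the features
are z-scored using training-fold statistics only, the SVM is trained
(C = 1, kernel width 1/(d * Var_train), sklearn's ``gamma='scale'``), and
accuracy is measured on the held-out fold.  Chance level in this balanced
binary task is 50%.

The result carries the per-fold accuracies, their mean, a Student-t 95%
confidence interval, and a one-sample t test of the fold accuracies against
chance (df = folds - 1).  Two cross-validation runs are compared with a
pooled-variance two-sample t test over the fold accuracies (df = 18 for
10 + 10 folds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import RatingTable

__all__ = [
    "BinaryLabeling",
    "CVResult",
    "tercile_split",
    "make_svm_rbf",
    "cv_svm_accuracy",
    "compare_cv",
]

MIN_RATED = 30


@dataclass(frozen=True)
class BinaryLabeling:
    """Disjoint low/high id sets of equal size for one rating term."""

    low_ids: tuple[str, ...]
    high_ids: tuple[str, ...]
    term: str
    degenerate: bool = False  # tie-dominated boundary

    def __post_init__(self) -> None:
        if set(self.low_ids) & set(self.high_ids):
            raise ValueError("low and high id sets overlap")
        if len(self.low_ids) != len(self.high_ids):
            raise ValueError("low and high id sets must have equal size")


def tercile_split(ratings: RatingTable, term: str) -> BinaryLabeling:
    """Lowest and highest thirds of images ranked by ``term``.

    Ranking is ascending with ties broken by stable id order; each class has
    floor(n/3) members.  A labeling whose class boundaries fall in large tie
    groups (> 5% of labeled items sharing a boundary value) is flagged
    ``degenerate``.
    """
    if term not in ratings.terms:
        raise KeyError(f"unknown rating term {term!r}")
    col = ratings.data[term].dropna()
    n = len(col)
    if n < MIN_RATED:
        raise ValueError(f"need >= {MIN_RATED} rated images, got {n}")
    order = col.sort_values(kind="stable")  # stable: ties broken by id order
    k = n // 3
    low = order.iloc[:k]
    high = order.iloc[-k:]
    boundary_vals = {low.iloc[-1], high.iloc[0]}
    n_tied = int(sum((col == v).sum() for v in boundary_vals))
    degenerate = n_tied > 0.05 * n
    if degenerate:
        warnings.warn(
            f"tercile split on {term!r} is tie-dominated: {n_tied}/{n} items share "
            "a boundary value",
            stacklevel=2,
        )
    return BinaryLabeling(
        tuple(str(i) for i in low.index),
        tuple(str(i) for i in high.index),
        term,
        degenerate,
    )


@dataclass(frozen=True)
class CVResult:
    """Fold accuracies with mean, 95% CI and one-sample t against chance."""

    fold_acc: tuple[float, ...]
    mean_acc: float
    ci95: tuple[float, float]
    t_stat: float
    df: int
    p_value: float
    seed: int | None = None
    hyperparams: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.fold_acc)


def make_svm_rbf(C: float = 1.0):
    """The classifier under evaluation: z-scoring + SVC(RBF, C=1, gamma='scale').

    With z-scored features gamma='scale' equals 1/(d * Var_train) = 1/d.
    Returned as an sklearn Pipeline, so it composes with sklearn tooling.
    """
    return make_pipeline(StandardScaler(), SVC(C=C, kernel="rbf", gamma="scale"))


def _result_from_folds(
    accs: np.ndarray, seed: int | None, hyperparams: dict
) -> CVResult:
    mean = float(accs.mean())
    df = len(accs) - 1
    se = accs.std(ddof=1) / np.sqrt(len(accs))
    tcrit = stats.t.ppf(0.975, df)
    if se > 0:
        t_stat = float((mean - 0.5) / se)
        p = float(2 * stats.t.sf(abs(t_stat), df))
    else:
        t_stat = np.inf if mean != 0.5 else 0.0
        p = 0.0 if mean != 0.5 else 1.0
    return CVResult(
        tuple(float(a) for a in accs),
        mean,
        (float(mean - tcrit * se), float(mean + tcrit * se)),
        t_stat,
        df,
        p,
        seed=seed,
        hyperparams=hyperparams,
    )


def cv_svm_accuracy(
    features: pd.DataFrame,
    labels: BinaryLabeling | tuple[np.ndarray, np.ndarray] | None = None,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold SVM-RBF accuracy over a labeled feature table.

    ``features`` is a feature table indexed by id and ``labels`` a
    :class:`BinaryLabeling`; alternatively pass raw arrays via ``X``/``y``
    (then ``features`` is ignored).  Per fold, z-scoring uses training-fold
    statistics only (the scaler lives inside the pipeline).
    """
    if X is None or y is None:
        if not isinstance(labels, BinaryLabeling):
            raise TypeError("labels must be a BinaryLabeling when X/y are not given")
        ids = list(labels.low_ids) + list(labels.high_ids)
        missing_rows = [i for i in ids if i not in features.index]
        if missing_rows:
            raise ValueError(f"ids without feature rows: {missing_rows[:5]}")
        sub = features.loc[ids]
        na = sub[sub.isna().any(axis=1)].index.tolist()
        if na:
            raise ValueError(f"missing feature values for ids: {na[:5]}")
        X = sub.to_numpy(dtype=float)
        y = np.r_[np.zeros(len(labels.low_ids)), np.ones(len(labels.high_ids))]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = np.empty(folds)
    for i, (tr, te) in enumerate(skf.split(X, y)):
        clf = make_svm_rbf(C=C)
        clf.fit(X[tr], y[tr])
        accs[i] = (clf.predict(X[te]) == y[te]).mean()
    return _result_from_folds(
        accs, seed, {"C": C, "kernel": "rbf", "gamma": "scale", "folds": folds}
    )


def compare_cv(a: CVResult, b: CVResult) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test over two sets of fold accuracies."""
    xa, xb = np.asarray(a.fold_acc), np.asarray(b.fold_acc)
    df = len(xa) + len(xb) - 2
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
        delta = xa.mean() - xb.mean()
        if delta == 0:
            return 0.0, df, 1.0
        return float(np.sign(delta) * np.inf), df, 0.0
    t, p = stats.ttest_ind(xa, xb, equal_var=True)
    return float(t), df, float(p)
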