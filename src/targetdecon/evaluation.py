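"""ROC/AUC computation and the stratified k-fold cross-validation harness.

AUC is the Mann-Whitney statistic: the probability that a uniformly
random positive outscores a uniformly random negative, with ties
credited 1/2.  Cross-validation pools the held-out scores of all folds
into a single ROC curve (per-fold AUCs are also reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = ["CVResult", "auc", "roc_curve", "kfold_cv"]


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUC needs at least one positive and one negative label")
    return scores, labels


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Equals 1 for perfect separation, 0.5 for random scores; ties between
    a positive and a negative count 1/2.
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 credit
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> np.ndarray:
    """ROC points (false-positive rate, true-positive rate).

    Thresholds sweep the unique scores in descending order; the returned
    array of shape (m, 2) starts at (0, 0) and ends at (1, 1), and its
    trapezoidal area equals :func:`auc` to numerical precision.
    """
    scores, labels = _check_scores_labels(scores, labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


@dataclass
class CVResult:
    """Outcome of a k-fold cross-validation run.

    ``fold_assignment`` maps each example to its held-out fold (1..k);
    ``scores`` are the held-out predictions, each produced by a model
    not trained on that example; ``roc_points``/``auc`` are pooled over
    all folds; ``fold_aucs`` may contain NaN for a fold whose held-out
    split lacks one class.
    """

    fold_assignment: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    roc_points: np.ndarray
    auc: float
    fold_aucs: list[float]
    seed: int


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    trainer: Callable[[np.ndarray, np.ndarray], object],
    scorer: Callable[[object, np.ndarray], np.ndarray],
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Seeded, label-stratified k-fold cross-validation.

    ``trainer(X_train, y_train)`` fits and returns a model;
    ``scorer(model, X_test)`` returns real-valued scores.  Folds
    partition the examples; stratification keeps per-fold positive
    counts within one of each other, so each fold contains both classes
    whenever that is feasible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError(f"need at least k={k} examples, got {len(y)}")

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.zeros(len(y), dtype=int)
    scores = np.full(len(y), np.nan)
    fold_aucs: list[float] = []
    for fold_idx, (train, test) in enumerate(splitter.split(X, y), start=1):
        assignment[test] = fold_idx
        model = trainer(X[train], y[train])
        scores[test] = np.asarray(scorer(model, X[test]), dtype=float).ravel()
        if 0 < y[test].sum() < len(test):
            fold_aucs.append(auc(scores[test], y[test]))
        else:
            fold_aucs.append(float("nan"))

    if not (0 < y.sum() < len(y)):
        raise ValueError("pooled labels are single-class; AUC undefined")
    if any(np.isnan(a) for a in fold_aucs):
        import warnings

        warnings.warn(
            "a fold's held-out split contains one class; its per-fold AUC is NaN "
            "(pooled AUC still defined)",
            stacklevel=2,
        )
    pooled_roc = roc_curve(scores, y)
    pooled_auc = auc(scores, y)
    return CVResult(
        fold_assignment=assignment,
        scores=scores,
        labels=y,
        roc_points=pooled_roc,
        auc=pooled_auc,
        fold_aucs=fold_aucs,
        seed=seed,
    )
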