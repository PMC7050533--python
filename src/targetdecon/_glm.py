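"""Shared regularized-logistic-regression fitting and C-grid selection.

Both classification stages use the same machinery: an L1- or
L2-regularized linear logistic model (liblinear solver) with the
penalty parameter C chosen by k-fold cross-validated AUC over a fixed
grid, ties broken toward the smallest C (strongest regularization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .evaluation import kfold_cv
from .io import LogisticModel

__all__ = ["TrainingConfig", "DEFAULT_C_GRID", "fit_logistic", "fit_with_c_selection"]

DEFAULT_C_GRID = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)


@dataclass
class TrainingConfig:
    """Hyperparameters shared by both classification stages.

    ``c_grid`` is the inverse-regularization-strength grid searched by
    cross-validated AUC; ``standardize`` z-scales features with
    training-data statistics (recomputed inside each CV training fold);
    all randomness (fold shuffling, solver) flows from ``seed``.
    """

    reg_type: str = "l1"
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    cv_folds: int = 5
    seed: int = 0
    standardize: bool = True
    class_weighting: str = "none"  # "none" | "balanced"
    tol: float = 1e-4
    max_iter: int = 1000
    per_protein: bool = False  # one CPI model per protein instead of per family

    def __post_init__(self) -> None:
        if self.reg_type not in ("l1", "l2"):
            raise ValueError("reg_type must be 'l1' or 'l2'")
        if len(self.c_grid) == 0 or any(c <= 0 for c in self.c_grid):
            raise ValueError("c_grid must be non-empty with positive entries")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError("class_weighting must be 'none' or 'balanced'")

    def replace(self, **kw) -> "TrainingConfig":
        from dataclasses import replace

        return replace(self, **kw)


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant feature: center only
    return mean, scale


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_order: list[str],
    C: float,
    config: TrainingConfig,
) -> LogisticModel:
    """Fit one regularized logistic model at a fixed C."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if len(set(y)) < 2:
        raise ValueError("training data contains a single class")
    mean = scale = None
    if config.standardize:
        mean, scale = _standardize_stats(X)
        X = (X - mean) / scale
    clf = LogisticRegression(
        l1_ratio=1.0 if config.reg_type == "l1" else 0.0,
        C=C,
        solver="liblinear",
        tol=config.tol,
        max_iter=config.max_iter,
        class_weight=None if config.class_weighting == "none" else "balanced",
        random_state=config.seed,
    )
    clf.fit(X, y)
    return LogisticModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        reg_type=config.reg_type,
        penalty_C=float(C),
        feature_order=list(feature_order),
        mean=mean,
        scale=scale,
    )


def fit_with_c_selection(
    X: np.ndarray,
    y: np.ndarray,
    feature_order: list[str],
    config: TrainingConfig,
) -> tuple[LogisticModel, pd.DataFrame]:
    """Choose C by cross-validated AUC, then refit on all the data.

    Returns the final model and a per-C report with columns
    (C, cv_auc, fold_aucs, selected).  Standardization statistics are
    learned inside each training fold during selection and on the full
    data for the final fit.  Ties in CV AUC go to the smallest C.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    rows = []
    best_C, best_auc = None, -np.inf
    for C in sorted(config.c_grid):
        cv = kfold_cv(
            X,
            y,
            trainer=lambda Xt, yt, C=C: fit_logistic(Xt, yt, feature_order, C, config),
            scorer=lambda m, Xe: m.predict_proba(Xe),
            k=config.cv_folds,
            seed=config.seed,
        )
        rows.append(dict(C=C, cv_auc=cv.auc, fold_aucs=list(cv.fold_aucs)))
        if cv.auc > best_auc:  # strict: first (smallest) C wins ties
            best_auc, best_C = cv.auc, C
    report = pd.DataFrame(rows)
    report["selected"] = report["C"] == best_C
    final = fit_logistic(X, y, feature_order, best_C, config)
    return final, report
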