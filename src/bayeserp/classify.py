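"""Target/nontarget classification with an RBF-kernel SVM.

Hyperparameters (cost C and kernel width, sklearn's ``gamma``) are selected
by mean validation accuracy over repeated stratified 80%/20% splits of the
calibration data; class weights are inversely proportional to class
frequency to counter the 3:1 nontarget:target imbalance of the four-arrow
paradigm.  Features are z-scored with training statistics inside every fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = ["DEFAULT_C_GRID", "DEFAULT_WIDTH_GRID", "select_hyperparameters", "train", "predict", "P300SVM"]

DEFAULT_C_GRID: tuple = tuple(4.0**k for k in range(-2, 7))
DEFAULT_WIDTH_GRID: tuple = tuple(4.0**k for k in range(-7, 2))


def _svm(C: float, width: float) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=C, gamma=width, class_weight="balanced")),
        ]
    )


def select_hyperparameters(
    features: np.ndarray,
    labels: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    width_grid=DEFAULT_WIDTH_GRID,
    n_splits: int = 20,
    split_fraction: float = 0.8,
    seed=None,
):
    """Grid search by repeated stratified 80/20 splitting.

    Returns ``(C, width, cv_report)`` where ``cv_report`` is a DataFrame of
    mean validation accuracy per grid point.  Ties break toward the smallest
    C, then the smallest width.  The same splits are reused for every grid
    point so the comparison is paired.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for hyperparameter selection")
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=split_fraction,
        random_state=None if seed is None else int(seed),
    )
    splits = list(splitter.split(X, y))
    rows = []
    best = None
    for C in sorted(C_grid):
        for width in sorted(width_grid):
            model = _svm(C, width)
            accs = []
            for tr, va in splits:
                m = clone(model)
                m.fit(X[tr], y[tr])
                accs.append(float(np.mean(m.predict(X[va]) == y[va])))
            mean_acc = float(np.mean(accs))
            rows.append({"C": C, "width": width, "mean_val_accuracy": mean_acc})
            if best is None or mean_acc > best[0] + 1e-12:
                best = (mean_acc, C, width)
    cv_report = pd.DataFrame(rows)
    return best[1], best[2], cv_report


def train(features, labels, C: float, width: float):
    """Fit the scaler + RBF SVM at fixed hyperparameters."""
    model = _svm(C, width)
    model.fit(np.asarray(features, dtype=float), np.asarray(labels))
    return model


def predict(model, features) -> np.ndarray:
    """Hard target/nontarget label per epoch."""
    return model.predict(np.asarray(features, dtype=float))


class P300SVM(ClassifierMixin, BaseEstimator):
    """RBF SVM with built-in repeated-split hyperparameter selection.

    With ``C``/``width`` left as None, ``fit`` first runs
    :func:`select_hyperparameters` on the training data, then refits the
    final scaler + SVM on all of it.  Fitted attributes: ``C_``, ``width_``,
    ``cv_report_``, ``model_``, ``classes_``.
    """

    def __init__(
        self,
        C: float | None = None,
        width: float | None = None,
        C_grid=DEFAULT_C_GRID,
        width_grid=DEFAULT_WIDTH_GRID,
        n_splits: int = 20,
        split_fraction: float = 0.8,
        random_state=None,
    ):
        self.C = C
        self.width = width
        self.C_grid = C_grid
        self.width_grid = width_grid
        self.n_splits = n_splits
        self.split_fraction = split_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        if self.C is None or self.width is None:
            C, width, self.cv_report_ = select_hyperparameters(
                X, y, C_grid=self.C_grid, width_grid=self.width_grid,
                n_splits=self.n_splits, split_fraction=self.split_fraction,
                seed=self.random_state,
            )
        else:
            C, width = float(self.C), float(self.width)
            self.cv_report_ = pd.DataFrame(
                [{"C": C, "width": width, "mean_val_accuracy": np.nan}]
            )
        self.C_, self.width_ = float(C), float(width)
        self.model_ = train(X, y, self.C_, self.width_)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} features, got shape {X.shape}"
            )
        return predict(self.model_, X)
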