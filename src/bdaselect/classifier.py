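"""Soft-margin SVM contract and cross-validated error estimation.

The classifier is the standard soft-margin SVM: minimize
``||w||^2 / 2 + C * sum_i max(0, 1 - y_i (w.x_i + b))`` with labels in
``{-1, +1}``; prediction is ``sign(w.x + b)`` (kernelized for RBF).  The
quadratic program is delegated to scikit-learn's libsvm wrapper; this module
owns the cross-validation protocol used inside the selection objective:
stratified K folds, per-fold z-score standardization fit on the training
fold only, deterministic under an integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_io import FeatureTable

logger = logging.getLogger(__name__)

__all__ = ["ClassifierSpec", "CVResult", "InfeasibleMaskError",
           "fit_predict", "cv_error", "stratified_folds"]


class InfeasibleMaskError(ValueError):
    """An empty feature mask cannot be trained; consumed by the objective."""


@dataclass(frozen=True)
class ClassifierSpec:
    """SVM hyperparameters.

    ``penalty`` is the soft-margin coefficient C (> 0).  The RBF bandwidth
    follows the ``1 / (p * Var(X))`` rule over the selected feature block
    (scikit-learn's ``gamma='scale'``), which is ~``1/p`` after per-fold
    standardization.
    """

    penalty: float = 1.0
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.penalty <= 0:
            raise ValueError("penalty C must be > 0")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")

    def make(self) -> SVC:
        return SVC(C=self.penalty, kernel=self.kernel, gamma="scale")


@dataclass
class CVResult:
    """Per-fold and mean cross-validated error of one feature mask."""

    fold_errors: list[float]
    mean_error: float = field(init=False)
    mean_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_error = float(np.mean(self.fold_errors))
        self.mean_accuracy = 1.0 - self.mean_error


def fit_predict(train: FeatureTable, test: FeatureTable,
                spec: ClassifierSpec) -> np.ndarray:
    """Fit the soft-margin SVM on ``train`` and predict ``test`` labels.

    Returns labels in ``{-1, +1}``.
    """
    if train.n_features == 0:
        raise InfeasibleMaskError("zero features")
    if not train.has_both_classes():
        raise ValueError("training set must contain both classes")
    if test.feature_names != train.feature_names:
        raise ValueError("test features must match train features")
    model = spec.make()
    model.fit(train.X, train.y)
    return model.predict(test.X).astype(np.int8)


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[tuple]:
    """Deterministic stratified K-fold indices; K is capped at the minority
    class count (with a warning) so every training split sees both classes."""
    counts = np.unique(y, return_counts=True)[1]
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        logger.warning("reducing folds from %d to %d (min class count)",
                       k, k_eff)
    if k_eff < 2:
        raise ValueError("need at least 2 members per class for CV")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns pass through unscaled
    return (train - mu) / sd, (test - mu) / sd


def cv_error(table: FeatureTable, mask: np.ndarray, spec: ClassifierSpec,
             k: int, seed: int) -> CVResult:
    """Stratified K-fold cross-validated error of the masked feature set.

    Standardization is fit on each training fold only.  Bit-for-bit
    reproducible for a fixed ``seed``; an all-zero mask raises
    :class:`InfeasibleMaskError`.
    """
    mask = np.asarray(mask)
    if mask.sum() == 0:
        raise InfeasibleMaskError("empty feature mask")
    cols = np.flatnonzero(mask)
    X, y = table.X[:, cols], table.y
    model = spec.make()
    errors = []
    for tr, te in stratified_folds(y, k, seed):
        if len(np.unique(y[tr])) < 2:  # cannot occur with stratified folds
            raise ValueError("single-class training fold")
        Xtr, Xte = _standardize(X[tr], X[te])
        model.fit(Xtr, y[tr])
        errors.append(float(np.mean(model.predict(Xte) != y[te])))
    return CVResult(fold_errors=errors)
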