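"""Binary classification metrics and the cross-validation harness.

Accuracy is (TP+TN)/(TP+FP+TN+FN); the F1 score is the harmonic mean of
precision and recall, computed in its count form 2*TP/(2*TP+FP+FN),
which stays defined when precision or recall individually is not. With
no true positives, no false positives and no false negatives F1 is
defined as 0 here.

Any object with ``fit(X, y)`` and ``predict(X)`` can be evaluated; two
reference classifiers are provided — the linear-kernel support vector
machine used for the k-fold protocol, and a small feed-forward network
(two hidden layers of 512 and 256 rectifier units, softmax-style output,
mini-batches of 50, 100 epochs). Folds are stratified by default: with
imbalanced cohorts, unstratified folds risk a held-out fold missing a
class entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred, positive=1) -> ConfusionCounts:
    """Four-cell confusion counts of a binary prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("accuracy of zero samples is undefined")
    return (c.tp + c.tn) / c.total


def f1_score(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 0.0
    return 2 * c.tp / denom


@dataclass
class CVResult:
    folds: list[dict]
    mean_f1: float
    mean_accuracy: float
    k: int
    seed: int | None


def kfold_cv(X, y, classifier, k: int = 10, seed: int | None = 0, stratified: bool = True) -> CVResult:
    """Evaluate a classifier by (stratified) k-fold cross-validation.

    The classifier is cloned per fold when it is an sklearn estimator,
    otherwise refit in place; fold splits depend only on (y, seed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"binary labels required, got classes {classes!r}")
    if stratified and counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify into k={k} folds"
        )
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    positive = classes.max()
    folds = []
    for fold_idx, (train, test) in enumerate(splitter.split(X, y)):
        try:
            model = clone(classifier)
        except TypeError:
            model = classifier
        model.fit(X[train], y[train])
        pred = np.asarray(model.predict(X[test]))
        c = confusion(y[test], pred, positive=positive)
        folds.append(
            {
                "fold": fold_idx,
                "n_test": int(test.size),
                "tp": c.tp,
                "tn": c.tn,
                "fp": c.fp,
                "fn": c.fn,
                "f1": f1_score(c),
                "accuracy": accuracy(c),
            }
        )
    return CVResult(
        folds=folds,
        mean_f1=float(np.mean([f["f1"] for f in folds])),
        mean_accuracy=float(np.mean([f["accuracy"] for f in folds])),
        k=k,
        seed=seed,
    )


def make_linear_classifier() -> SVC:
    """The linear-kernel SVM used by the k-fold protocol."""
    return SVC(kernel="linear")


def make_mlp_classifier(seed: int | None = 0) -> MLPClassifier:
    """Small feed-forward network: 512 and 256 rectifier units, batch 50,
    100 epochs."""
    return MLPClassifier(
        hidden_layer_sizes=(512, 256),
        activation="relu",
        batch_size=50,
        max_iter=100,
        random_state=seed,
    )


__all__ = [
    "ConfusionCounts",
    "confusion",
    "accuracy",
    "f1_score",
    "CVResult",
    "kfold_cv",
    "make_linear_classifier",
    "make_mlp_classifier",
]
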