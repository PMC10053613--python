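"""Classifiers, evaluation metrics and the train/test split protocol.

The native classifier is a Euclidean majority-vote k-NN (k = 5 by default),
implemented here and exposed as a scikit-learn-compatible estimator.
Alternative classifiers — LDA (svd solver), decision tree (gini), random
forest (100 estimators, gini) and L2 logistic regression — are registry
entries configured on top of scikit-learn.

Evaluation uses a stratified 80/20 holdout (k-fold cross-validation is
available as an option), confusion counts with class 1 as the positive
class, accuracy / sensitivity / specificity, and AUC computed from the
classifier's ranking scores; for k-NN the score of a query is its fraction
of positive votes among the k neighbours.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import FeatureTable

__all__ = [
    "KNNConfig",
    "KNeighborsMajorityClassifier",
    "ConfusionCounts",
    "Metrics",
    "MetricUndefinedWarning",
    "SplitSpec",
    "euclidean_distance",
    "knn_predict",
    "make_classifier",
    "make_split",
    "confusion_from_predictions",
    "metrics",
    "evaluate_classifier",
]

POSITIVE_CLASS = 1

CLASSIFIER_REGISTRY = ("knn", "lda", "dt", "rf", "lr")


class MetricUndefinedWarning(UserWarning):
    """A confusion-matrix denominator was zero; the metric is NaN."""


@dataclasses.dataclass(frozen=True)
class KNNConfig:
    k: int = 5
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric != "euclidean":
            raise ValueError("only the euclidean metric is supported")


def euclidean_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance sqrt(sum_i (p_i - q_i)^2)."""
    p, q = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have the same length")
    return float(np.sqrt(np.sum((p - q) ** 2)))


class KNeighborsMajorityClassifier(ClassifierMixin, BaseEstimator):
    """Majority-vote k-nearest-neighbour classifier (Euclidean distance).

    Vote ties (possible only for even k or >2 classes) are broken toward the
    tied class whose voting neighbours lie closer in total, then toward the
    lowest class label — a deterministic, distance-respecting rule.
    ``predict_proba`` returns per-class vote fractions among the k
    neighbours, which also serve as ranking scores for AUC.
    """

    def __init__(self, k: int = 5, metric: str = "euclidean"):
        self.k = k
        self.metric = metric

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        KNNConfig(self.k, self.metric)  # validates hyperparameters
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds the {X.shape[0]} training samples")
        self.classes_, self._y_idx = np.unique(y, return_inverse=True)
        self.X_ = X
        self.y_ = y
        return self

    def _neighbors(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Indices and distances of the k nearest training points per query."""
        D = cdist(X, self.X_)
        if self.k < self.X_.shape[0]:
            part = np.argpartition(D, self.k - 1, axis=1)[:, : self.k]
        else:
            part = np.tile(np.arange(self.X_.shape[0]), (X.shape[0], 1))
        return part, np.take_along_axis(D, part, axis=1)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        idx, _ = self._neighbors(X)
        votes = self._y_idx[idx]  # (n_queries, k) class indices
        proba = np.empty((X.shape[0], len(self.classes_)))
        for c in range(len(self.classes_)):
            proba[:, c] = (votes == c).mean(axis=1)
        return proba

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        idx, dist = self._neighbors(X)
        votes = self._y_idx[idx]
        out = np.empty(X.shape[0], dtype=self.classes_.dtype)
        for q in range(X.shape[0]):
            counts = np.bincount(votes[q], minlength=len(self.classes_))
            top = counts.max()
            tied = np.flatnonzero(counts == top)
            if len(tied) == 1:
                out[q] = self.classes_[tied[0]]
                continue
            # tie: smaller summed distance of the tied class's neighbours wins
            sums = [dist[q][votes[q] == c].sum() for c in tied]
            best = tied[np.flatnonzero(np.isclose(sums, min(sums)))[0]]
            out[q] = self.classes_[best]
        return out


def knn_predict(train: FeatureTable, query: np.ndarray, cfg: KNNConfig = KNNConfig()) -> int:
    """Classify one query vector against a training table (thin wrapper)."""
    clf = KNeighborsMajorityClassifier(k=cfg.k, metric=cfg.metric)
    clf.fit(train.X, train.y)
    return int(clf.predict(np.asarray(query, dtype=float).reshape(1, -1))[0])


def make_classifier(spec: Any, random_state: int | None = None) -> BaseEstimator:
    """Build a classifier from a registry name, (name, params) or estimator.

    Registry: ``knn`` (native, k=5), ``lda`` (svd solver), ``dt`` (gini),
    ``rf`` (100 estimators, gini) and ``lr`` (L2 penalty, lbfgs). Tree-based
    entries take their random state from ``random_state`` so repeated runs
    are reproducible.
    """
    if isinstance(spec, BaseEstimator):
        est = clone(spec)
        if "random_state" in est.get_params():
            est.set_params(random_state=random_state)
        return est
    params: dict = {}
    if isinstance(spec, tuple):
        spec, params = spec[0], dict(spec[1])
    name = str(spec).lower()
    if name == "knn":
        return KNeighborsMajorityClassifier(**{"k": 5, **params})
    if name == "lda":
        return LinearDiscriminantAnalysis(**{"solver": "svd", **params})
    if name == "dt":
        return DecisionTreeClassifier(
            **{"criterion": "gini", "random_state": random_state, **params}
        )
    if name == "rf":
        return RandomForestClassifier(
            **{"n_estimators": 100, "criterion": "gini", "random_state": random_state, **params}
        )
    if name == "lr":
        # L2 penalty is the sklearn default (the explicit flag is deprecated)
        return LogisticRegression(**{"solver": "lbfgs", "C": 1.0, **params})
    raise ValueError(f"unknown classifier {spec!r}; choose from {CLASSIFIER_REGISTRY}")


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Stratified holdout (default 80/20) or, when n_folds is set, k-fold CV."""

    test_size: float = 0.2
    n_folds: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_size < 1:
            raise ValueError("test_size must lie in (0, 1)")
        if self.n_folds is not None and self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def make_split(y: np.ndarray, split: SplitSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Return (train_idx, test_idx) partitions, each with both classes."""
    y = np.asarray(y)
    if split.n_folds is not None:
        cv = StratifiedKFold(n_splits=split.n_folds, shuffle=True, random_state=split.seed)
    else:
        cv = StratifiedShuffleSplit(n_splits=1, test_size=split.test_size, random_state=split.seed)
    parts = [(tr, te) for tr, te in cv.split(np.zeros((len(y), 1)), y)]
    for tr, te in parts:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("degenerate split: a partition lacks one of the classes")
    return parts


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive: int = POSITIVE_CLASS
) -> ConfusionCounts:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    pos_t, pos_p = y_true == positive, y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity tp/(tp+fn) and specificity tn/(tn+fp).

    A zero denominator yields NaN and a :class:`MetricUndefinedWarning` —
    never a silent zero.
    """

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", MetricUndefinedWarning,
                          stacklevel=3)
            return math.nan
        return num / den

    return Metrics(
        accuracy=ratio(c.tp + c.tn, c.total, "accuracy"),
        sensitivity=ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=ratio(c.tn, c.tn + c.fp, "specificity"),
    )


def _positive_scores(clf: BaseEstimator, X: np.ndarray) -> np.ndarray:
    """Ranking score for the positive class from proba or decision function."""
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        col = int(np.flatnonzero(clf.classes_ == POSITIVE_CLASS)[0])
        return proba[:, col]
    score = clf.decision_function(X)
    # decision_function orients toward classes_[1]; flip if positive is classes_[0]
    return score if clf.classes_[1] == POSITIVE_CLASS else -score


def evaluate_classifier(
    table: FeatureTable,
    mask: np.ndarray,
    classifier_spec: Any = "knn",
    split: SplitSpec = SplitSpec(),
    seed: int | None = None,
) -> tuple[ConfusionCounts, float]:
    """Train on the stratified training partition restricted to ``mask`` and
    evaluate the held-out partition; returns confusion counts and AUC.

    With ``split.n_folds`` set, counts are summed and AUC averaged over
    folds. ``seed`` feeds the classifier's own randomness (RF/DT).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no features")
    sub = table.restrict(mask)
    tp = tn = fp = fn = 0
    aucs = []
    for tr, te in make_split(sub.y, split):
        clf = make_classifier(classifier_spec, random_state=seed)
        clf.fit(sub.X[tr], sub.y[tr])
        y_pred = clf.predict(sub.X[te])
        c = confusion_from_predictions(sub.y[te], y_pred)
        tp, tn, fp, fn = tp + c.tp, tn + c.tn, fp + c.fp, fn + c.fn
        scores = _positive_scores(clf, sub.X[te])
        aucs.append(roc_auc_score((sub.y[te] == POSITIVE_CLASS).astype(int), scores))
    return ConfusionCounts(tp, tn, fp, fn), float(np.mean(aucs))
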