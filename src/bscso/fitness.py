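"""Wrapper fitness: KNN error rate plus a subset-size penalty.

The objective being minimized over feature subsets is

    fitness = alpha * ER + beta * |S| / C

where ``ER`` is the error rate of a k-nearest-neighbor classifier trained
on the training partition and scored on the validation partition using only
the selected columns, ``|S|`` is the number of selected features and ``C``
the total.  ``alpha`` dominates (0.99 by default) so accuracy drives the
search, with the size term breaking ties toward smaller subsets.

KNN uses Euclidean distance on (min-max normalized) features and majority
vote; voting ties are broken by the nearest single neighbor's label, then
by the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FitnessWeights",
    "EvaluationContext",
    "SubsetEvaluation",
    "knn_error_rate",
    "wrapper_fitness",
    "test_accuracy",
    "fitness_function",
]


@dataclass(frozen=True)
class FitnessWeights:
    """Weights of the error term (alpha) and the size term (beta)."""

    alpha: float = 0.99
    beta: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")


@dataclass
class EvaluationContext:
    """Frozen data partitions and settings the wrapper fitness closes over."""

    train_features: np.ndarray
    train_labels: np.ndarray
    validation_features: np.ndarray
    validation_labels: np.ndarray
    k: int = 5
    weights: FitnessWeights = field(default_factory=FitnessWeights)

    def __post_init__(self) -> None:
        self.train_features = np.asarray(self.train_features, dtype=float)
        self.validation_features = np.asarray(self.validation_features, dtype=float)
        self.train_labels = np.asarray(self.train_labels)
        self.validation_labels = np.asarray(self.validation_labels)
        if self.train_features.shape[1] != self.validation_features.shape[1]:
            raise ValueError("train and validation feature counts differ")
        if self.train_features.shape[0] != self.train_labels.shape[0]:
            raise ValueError("train labels misaligned with features")
        if self.validation_features.shape[0] != self.validation_labels.shape[0]:
            raise ValueError("validation labels misaligned with features")
        if not 1 <= self.k <= self.train_features.shape[0]:
            raise ValueError("k must satisfy 1 <= k <= n_train")

    @property
    def n_features(self) -> int:
        return self.train_features.shape[1]


@dataclass(frozen=True)
class SubsetEvaluation:
    """Error rate, subset size and combined fitness of one bit vector."""

    error_rate: float
    n_selected: int
    fitness: float


def _knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query_X: np.ndarray,
    k: int,
) -> np.ndarray:
    """Majority-vote KNN on an explicit Euclidean distance matrix.

    Ties in the vote go to the nearest neighbor's label if it is among the
    tied classes, else to the lowest tied class index.  Neighbor order on
    exact distance ties is stable in training-row order.
    """
    dist = cdist(query_X, train_X)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    neigh_labels = train_y[order]
    n_classes = int(train_y.max()) + 1
    out = np.empty(query_X.shape[0], dtype=train_y.dtype)
    for i in range(query_X.shape[0]):
        counts = np.bincount(neigh_labels[i], minlength=n_classes)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if winners.size == 1:
            out[i] = winners[0]
        elif neigh_labels[i, 0] in winners:
            out[i] = neigh_labels[i, 0]
        else:
            out[i] = winners[0]
    return out


def _selected_columns(bits: np.ndarray) -> np.ndarray:
    bits = np.asarray(bits)
    sel = np.flatnonzero(bits)
    if sel.size == 0:
        raise ValueError("bit vector selects no features; repair it first")
    return sel


def knn_error_rate(context: EvaluationContext, bits: np.ndarray) -> float:
    """Validation error rate of KNN restricted to the selected features."""
    sel = _selected_columns(bits)
    pred = _knn_predict(
        context.train_features[:, sel],
        context.train_labels,
        context.validation_features[:, sel],
        context.k,
    )
    return float(np.mean(pred != context.validation_labels))


def wrapper_fitness(context: EvaluationContext, bits: np.ndarray) -> SubsetEvaluation:
    """Evaluate ``alpha * ER + beta * |S| / C`` for one bit vector."""
    sel = _selected_columns(bits)
    er = knn_error_rate(context, bits)
    w = context.weights
    fit = w.alpha * er + w.beta * sel.size / context.n_features
    return SubsetEvaluation(error_rate=er, n_selected=int(sel.size), fitness=fit)


def fitness_function(context: EvaluationContext):
    """Return a ``bits -> float`` closure suitable for the optimizer."""

    def fn(bits: np.ndarray) -> float:
        return wrapper_fitness(context, bits).fitness

    return fn


def test_accuracy(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    test_labels: np.ndarray,
    bits: np.ndarray,
    k: int = 5,
) -> float:
    """Held-out accuracy of the selected subset: 1 - KNN test error rate."""
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    if not 1 <= k <= train_features.shape[0]:
        raise ValueError("k must satisfy 1 <= k <= n_train")
    sel = _selected_columns(bits)
    pred = _knn_predict(
        train_features[:, sel], np.asarray(train_labels), test_features[:, sel], k
    )
    return float(np.mean(pred == np.asarray(test_labels)))
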