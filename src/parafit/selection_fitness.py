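"""Gene-selection fitness: F(x) = w1 * A(x) + w2 * (M - R(x)) / M.

A(x) is the leave-one-out cross-validation accuracy of a pluggable
classifier on the samples restricted to the selected genes; R(x) is the
number of selected genes. F is maximized: high accuracy with few genes.

The default classifier is a deterministic nearest-centroid rule
(per-class mean, Euclidean distance, ties broken toward the class that
sorts first). Any object with ``fit(X, y)`` / ``predict(X)`` can be
plugged in instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .expression_io import GeneSubset, LabeledDataset

__all__ = [
    "SelectionFitnessConfig",
    "AccuracyResult",
    "NearestCentroidClassifier",
    "resolve_classifier",
    "subset_fitness",
    "loocv_accuracy",
    "evaluate_subset",
]


@dataclass(frozen=True)
class SelectionFitnessConfig:
    """Weights for the two fitness terms and the total gene count M."""

    w1: float
    w2: float
    M: int

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError(f"weights must be non-negative, got w1={self.w1}, w2={self.w2}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")


@dataclass(frozen=True)
class AccuracyResult:
    """LOOCV accuracy A plus the per-fold correctness vector."""

    A: float
    per_fold: np.ndarray

    def __post_init__(self) -> None:
        per_fold = np.asarray(self.per_fold, dtype=bool)
        object.__setattr__(self, "per_fold", per_fold)
        if abs(self.A - float(per_fold.mean())) > 1e-12:
            raise ValueError("A must equal the mean of per_fold")


class NearestCentroidClassifier:
    """Nearest class-centroid classifier (Euclidean distance).

    Equidistant centroids resolve to the class that is first in sorted
    class-label order (``np.unique`` sorts; ``argmin`` takes the first
    minimum), so predictions are fully deterministic.
    """

    def fit(self, X: np.ndarray, y) -> "NearestCentroidClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.centroids_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


_CLASSIFIERS: dict[str, Callable[[], object]] = {
    "nearest-centroid": NearestCentroidClassifier,
}


def resolve_classifier(spec) -> Callable[[], object]:
    """Turn a classifier spec into a factory of fresh estimators.

    Accepts a registered name, a class / zero-arg factory, or an already
    constructed estimator (reused and refit at each fold).
    """
    if isinstance(spec, str):
        try:
            return _CLASSIFIERS[spec]
        except KeyError:
            raise ValueError(
                f"unknown classifier {spec!r}; available: {sorted(_CLASSIFIERS)}"
            ) from None
    if hasattr(spec, "fit") and hasattr(spec, "predict"):
        return lambda: spec
    if callable(spec):
        return spec
    raise ValueError(f"cannot interpret classifier spec {spec!r}")


def subset_fitness(A: float, R: int, cfg: SelectionFitnessConfig) -> float:
    """F = w1 * A + w2 * (M - R) / M, to be maximized."""
    if not 0.0 <= A <= 1.0:
        raise ValueError(f"accuracy A must lie in [0, 1], got {A}")
    if not 0 <= R <= cfg.M:
        raise ValueError(f"R must lie in [0, M={cfg.M}], got {R}")
    return cfg.w1 * A + cfg.w2 * (cfg.M - R) / cfg.M


def loocv_accuracy(d: LabeledDataset, x: GeneSubset,
                   classifier="nearest-centroid") -> AccuracyResult:
    """Leave-one-out cross-validation accuracy on the selected genes.

    For each sample i the classifier is trained on the other N-1 samples
    restricted to the genes in ``x`` and then predicts sample i.
    Deterministic given (dataset, subset, classifier spec).
    """
    if x.M != d.M:
        raise ValueError(f"mask length {x.M} does not match dataset M={d.M}")
    if x.R < 1:
        raise ValueError("no genes selected")
    if d.N < 2:
        raise ValueError(f"need at least 2 samples, got {d.N}")
    if len(set(d.labels)) < 2:
        raise ValueError("need at least 2 classes for classification")

    factory = resolve_classifier(classifier)
    X = d.matrix.values[:, x.mask]
    y = np.asarray(d.labels)
    per_fold = np.zeros(d.N, dtype=bool)
    for i in range(d.N):
        keep = np.arange(d.N) != i
        clf = factory()
        clf.fit(X[keep], y[keep])
        pred = np.asarray(clf.predict(X[i:i + 1]))
        per_fold[i] = pred.ravel()[0] == y[i]
    return AccuracyResult(A=float(per_fold.mean()), per_fold=per_fold)


def evaluate_subset(d: LabeledDataset, x: GeneSubset,
                    cfg: SelectionFitnessConfig,
                    classifier="nearest-centroid") -> float:
    """F(x) with A(x) computed by LOOCV on the dataset."""
    acc = loocv_accuracy(d, x, classifier)
    return subset_fitness(acc.A, x.R, cfg)
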