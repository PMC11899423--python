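"""Back-end classifiers for extracted features, and evaluation utilities.

KNN and Gaussian naive Bayes operate on the low-dimensional features the
extractors produce (the C-1 CLDA coordinates, or the PCA+LDA Fisher
coordinates).  Both are written out explicitly because the tie-break and
degeneracy rules matter on these features: all training samples of a class
can share an identical CLDA projection, producing exact distance ties for
KNN and zero within-class variance for naive Bayes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import FitError, ParameterError, SchemaError

__all__ = [
    "FeatureSet",
    "ConfusionMatrix",
    "KNNClassifier",
    "GaussianNaiveBayes",
    "knn_predict",
    "nb_fit",
    "nb_predict",
    "evaluate",
]


@dataclass
class FeatureSet:
    """Extracted feature matrix with (optional) labels and the class order."""

    features: np.ndarray
    labels: np.ndarray | None = None
    class_order: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=str)
            if self.labels.shape[0] != self.features.shape[0]:
                raise SchemaError("labels/features length mismatch")
            if self.class_order is None:
                self.class_order = np.unique(self.labels)


class KNNClassifier(ClassifierMixin, BaseEstimator):
    """K-nearest-neighbour majority vote with deterministic tie-breaks.

    Euclidean distances; a vote tie among classes is resolved by the larger
    summed inverse distance of the tied classes' neighbours, and a residual
    tie by the lowest class index.  Default k = 7 (the K at which the
    boosted extractor's accuracy peaks in the K-sweep analysis).
    """

    def __init__(self, k: int = 7):
        self.k = k

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise SchemaError(f"{y.shape[0]} labels for {X.shape[0]} samples")
        if not 1 <= int(self.k) <= X.shape[0]:
            raise ParameterError(
                f"k must be in [1, n_train={X.shape[0]}], got {self.k}"
            )
        self.X_ = X
        self.classes_ = np.unique(y)
        self.y_idx_ = np.searchsorted(self.classes_, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"{X.shape[1]} features, fitted with {self.n_features_in_}"
            )
        k = int(self.k)
        D = cdist(X, self.X_)
        C = self.classes_.shape[0]
        out = np.empty(X.shape[0], dtype=int)
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        for i in range(X.shape[0]):
            nn = order[i]
            lab = self.y_idx_[nn]
            counts = np.bincount(lab, minlength=C)
            best = counts.max()
            tied = np.flatnonzero(counts == best)
            if tied.size > 1:
                with np.errstate(divide="ignore"):
                    inv = 1.0 / D[i, nn]
                strength = np.array(
                    [inv[lab == c].sum() for c in tied]
                )
                tied = tied[strength == strength.max()]
            out[i] = tied[0]
        return self.classes_[out]


class GaussianNaiveBayes(ClassifierMixin, BaseEstimator):
    """Gaussian naive Bayes on continuous features.

    Priors are class frequencies; each feature is modelled per class by an
    independent Gaussian (sample variance, divisor n-1).  Variances are
    floored at ``var_floor_rel * max variance`` because extracted features
    can be exactly constant within a class; posteriors are computed in the
    log domain and ties go to the lowest class index.
    """

    def __init__(self, var_floor_rel: float = 1e-9):
        self.var_floor_rel = var_floor_rel

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise SchemaError(f"{y.shape[0]} labels for {X.shape[0]} samples")
        self.classes_ = np.unique(y)
        C = self.classes_.shape[0]
        p = X.shape[1]
        self.priors_ = np.empty(C)
        self.theta_ = np.empty((C, p))
        self.var_ = np.empty((C, p))
        for i, c in enumerate(self.classes_):
            block = X[y == c]
            if block.shape[0] < 2:
                raise FitError(
                    f"class {c!r} has {block.shape[0]} sample(s); need >= 2 "
                    "to estimate a variance"
                )
            self.priors_[i] = block.shape[0] / X.shape[0]
            self.theta_[i] = block.mean(axis=0)
            self.var_[i] = block.var(axis=0, ddof=1)
        floor = self.var_floor_rel * max(float(self.var_.max()), 0.0)
        if floor <= 0.0:
            floor = 1e-12
        self.var_ = np.maximum(self.var_, floor)
        self.n_features_in_ = p
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"{X.shape[1]} features, fitted with {self.n_features_in_}"
            )
        ll = np.empty((X.shape[0], self.classes_.shape[0]))
        for i in range(self.classes_.shape[0]):
            diff = X - self.theta_[i]
            ll[:, i] = (
                np.log(self.priors_[i])
                - 0.5 * np.sum(np.log(2.0 * np.pi * self.var_[i]))
                - 0.5 * np.sum(diff ** 2 / self.var_[i], axis=1)
            )
        return ll

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


@dataclass
class ConfusionMatrix:
    """Cross-tabulated counts, rows = truth, columns = predicted."""

    counts: np.ndarray
    class_order: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.class_order,
                            columns=self.class_order)

    def __str__(self) -> str:
        return self.to_dataframe().to_string()


# -- functional surface ----------------------------------------------------

def knn_predict(train: FeatureSet, test: FeatureSet, k: int = 7) -> np.ndarray:
    if train.labels is None:
        raise SchemaError("training FeatureSet must be labelled")
    clf = KNNClassifier(k=k).fit(train.features, train.labels)
    return clf.predict(test.features)


def nb_fit(train: FeatureSet) -> GaussianNaiveBayes:
    if train.labels is None:
        raise SchemaError("training FeatureSet must be labelled")
    return GaussianNaiveBayes().fit(train.features, train.labels)


def nb_predict(model: GaussianNaiveBayes, test: FeatureSet) -> np.ndarray:
    return model.predict(test.features)


def evaluate(pred, truth, class_order=None):
    """Accuracy and confusion matrix of a prediction.

    Returns ``(accuracy, ConfusionMatrix)``; counts are tabulated in
    ``class_order`` (default: sorted union of labels seen).
    """
    pred = np.asarray(pred, dtype=str)
    truth = np.asarray(truth, dtype=str)
    if pred.shape[0] != truth.shape[0]:
        raise SchemaError(f"{pred.shape[0]} predictions for {truth.shape[0]} truths")
    if pred.shape[0] == 0:
        raise ParameterError("cannot evaluate an empty prediction")
    if class_order is None:
        class_order = np.unique(np.concatenate([truth, pred]))
    else:
        class_order = np.asarray(class_order, dtype=str)
        known = set(class_order.tolist())
        stray = [l for l in np.concatenate([truth, pred]) if l not in known]
        if stray:
            raise SchemaError(f"label(s) {sorted(set(stray))} not in class order")
    lookup = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((class_order.shape[0],) * 2, dtype=int)
    for t, p in zip(truth, pred):
        counts[lookup[t], lookup[p]] += 1
    cm = ConfusionMatrix(counts=counts, class_order=class_order)
    return cm.accuracy, cm
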