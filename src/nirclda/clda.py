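"""Common-vectors linear discriminant analysis (CLDA).

Classical Fisher LDA is undefined in the small-sample regime
``d > M - C`` (more channels than within-class degrees of freedom), where
the within-class scatter

    S_W = sum_i sum_m (x_m^i - mu_i)(x_m^i - mu_i)^T

is singular.  CLDA discriminates in the *null space* of S_W instead:

1.  An orthonormal basis Q of range(S_W) is obtained from the non-zero
    eigenpairs of the M x M Gram matrix A^T A, where the columns of the
    d x M matrix A are the class-centered training samples — the d x d
    scatter itself is never formed.
2.  Projecting any one sample of a class onto null(S_W),
    ``x_com = x - Q Q^T x``, yields that class's *common vector*: the
    result is the same for every sample of the class, because within-class
    differences lie entirely in range(S_W).
3.  The scatter of the C common vectors (rank at most C-1) is
    eigendecomposed — again via its C x C Gram matrix — and its non-null
    eigenvectors form the projection matrix W with (generically) C-1
    orthonormal columns, all lying in null(S_W).

The *discriminative common vectors* ``Omega_i = W^T x_m^i`` (independent
of m, by the same exact-projection identity) are the class templates; a
test sample is assigned to the class whose Omega is nearest in Euclidean
distance.  On the training set this classifier is exact whenever the
common vectors are pairwise distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .dataset import SpectralDataset
from .exceptions import DegenerateDataError, ParameterError, RegimeError, SchemaError

__all__ = [
    "ScatterBasis",
    "CommonVectorsLDA",
    "within_class_scatter",
    "between_class_scatter",
    "total_scatter",
    "scatter_basis",
    "common_vector",
    "fit",
    "project",
    "classify_nearest_common_vector",
]


# -- scatter-matrix utilities (d x d; for small-d oracles and the PCA+LDA
#    baseline — CLDA itself never forms these) -----------------------------

def within_class_scatter(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """S_W = sum over classes of outer products of class-centered samples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    A = _centered_rows(X, y)
    return A.T @ A


def between_class_scatter(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """S_B = sum_i n_i (mu_i - mu)(mu_i - mu)^T."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mu = X.mean(axis=0)
    S = np.zeros((X.shape[1], X.shape[1]))
    for c in np.unique(y):
        idx = y == c
        diff = X[idx].mean(axis=0) - mu
        S += idx.sum() * np.outer(diff, diff)
    return S


def total_scatter(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """S_T = sum_m (x_m - mu)(x_m - mu)^T = S_W + S_B (utility only)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc


def _centered_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rows of A^T: every sample minus its class mean, classes in sorted order."""
    parts = []
    for c in np.unique(y):
        block = X[y == c]
        parts.append(block - block.mean(axis=0))
    return np.vstack(parts)


@dataclass
class ScatterBasis:
    """Orthonormal basis of range(S_W) with the non-zero eigenvalues.

    ``Q`` has shape (d, rank); ``rank <= M - C`` always holds because each
    class's centered samples satisfy one linear constraint (they sum to
    zero).
    """

    Q: np.ndarray
    rank: int
    eigenvalues: np.ndarray


def _range_basis(A_rows: np.ndarray, rank_tol: float | None = None) -> ScatterBasis:
    """Eigen-basis of span(A columns) from the small Gram matrix.

    ``A_rows`` is A^T (M x d).  Eigenvalues of A^T A below
    ``M * eps * lambda_max`` are treated as zero (standard numerical-rank
    tolerance).  Columns of Q are A v / sqrt(lambda), orthonormal by
    construction.
    """
    M = A_rows.shape[0]
    d = A_rows.shape[1]
    if M == 0:
        return ScatterBasis(Q=np.zeros((d, 0)), rank=0, eigenvalues=np.zeros(0))
    G = A_rows @ A_rows.T
    evals, evecs = np.linalg.eigh(G)
    lmax = float(evals[-1]) if evals.size else 0.0
    tol = rank_tol if rank_tol is not None else M * np.finfo(float).eps * max(lmax, 0.0)
    keep = np.flatnonzero(evals > max(tol, 0.0))[::-1]  # descending
    lam = evals[keep]
    Q = A_rows.T @ (evecs[:, keep] / np.sqrt(lam)) if keep.size else np.zeros((d, 0))
    return ScatterBasis(Q=Q, rank=int(keep.size), eigenvalues=lam)


class CommonVectorsLDA(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Discriminative common vectors classifier / feature extractor.

    Parameters
    ----------
    rank_tol : float, optional
        Absolute eigenvalue cutoff for the numerical rank of the scatter
        Gram matrices; default ``M * eps * lambda_max``.
    degenerate_tol : float
        Two classes whose common vectors are closer than
        ``degenerate_tol * max ||x_com||`` are reported as indistinguishable.

    Attributes
    ----------
    classes_ : ndarray of shape (C,)
        Sorted class labels.
    basis_ : ScatterBasis
        Orthonormal basis Q of range(S_W) and its eigenvalues.
    common_vectors_ : ndarray of shape (C, d)
        Per-class common vectors x_com.
    mu_com_ : ndarray of shape (d,)
        Mean of the common vectors.
    scalings_ : ndarray of shape (d, n_components_)
        Projection matrix W; orthonormal columns in null(S_W),
        generically C-1 of them.
    omegas_ : ndarray of shape (C, n_components_)
        Discriminative common vectors Omega_i = W^T x_com_i.
    """

    def __init__(self, rank_tol: float | None = None,
                 degenerate_tol: float = 1e-8):
        self.rank_tol = rank_tol
        self.degenerate_tol = degenerate_tol

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        M, d = X.shape
        if y.shape[0] != M:
            raise SchemaError(f"{y.shape[0]} labels for {M} samples")
        classes = np.unique(y)
        C = classes.shape[0]
        if C < 2:
            raise ParameterError("need at least 2 classes")
        if d <= M - C:
            raise RegimeError(
                f"d={d} <= M-C={M - C}: the within-class scatter has no "
                "null space. CLDA needs the small-sample regime; reduce the "
                "training-set size or use more channels (or the PCA+LDA "
                "baseline)."
            )
        self.classes_ = classes
        self.n_features_in_ = d
        self.basis_ = _range_basis(_centered_rows(X, y), self.rank_tol)
        Q = self.basis_.Q

        # one representative per class; the invariance theorem makes the
        # choice arbitrary (and the test suite asserts it)
        reps = np.vstack([X[np.flatnonzero(y == c)[0]] for c in classes])
        self.common_vectors_ = reps - (reps @ Q) @ Q.T

        norms = np.linalg.norm(self.common_vectors_, axis=1)
        scale = max(float(norms.max()), 1e-300)
        D = cdist(self.common_vectors_, self.common_vectors_)
        for i in range(C):
            for j in range(i + 1, C):
                if D[i, j] < self.degenerate_tol * scale:
                    raise DegenerateDataError(
                        f"classes {classes[i]!r} and {classes[j]!r} have "
                        f"coinciding common vectors (distance {D[i, j]:.3e})"
                    )

        self.mu_com_ = self.common_vectors_.mean(axis=0)
        com_basis = _range_basis(self.common_vectors_ - self.mu_com_,
                                 self.rank_tol)
        W = com_basis.Q  # at most C-1 columns
        # fix signs: largest-magnitude entry of each column positive
        for k in range(W.shape[1]):
            j = int(np.argmax(np.abs(W[:, k])))
            if W[j, k] < 0:
                W[:, k] = -W[:, k]
        self.scalings_ = W
        self.n_components_ = W.shape[1]
        self.eigenvalues_ = com_basis.eigenvalues
        self.omegas_ = self.common_vectors_ @ W
        return self

    def _check_X(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"{X.shape[1]} channels, model fitted with {self.n_features_in_}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        """Project onto the discriminant subspace: Omega = W^T x, row-wise."""
        return self._check_X(X) @ self.scalings_

    def predict(self, X) -> np.ndarray:
        """Nearest discriminative common vector, Euclidean distance.

        Ties go to the lowest class index (argmin convention)."""
        D = cdist(self.transform(X), self.omegas_)
        return self.classes_[np.argmin(D, axis=1)]


# -- spec-surface wrappers over the estimator ------------------------------

def scatter_basis(train: SpectralDataset, rank_tol: float | None = None) -> ScatterBasis:
    """Range-space basis of the within-class scatter of a training set."""
    M, d = train.X.shape
    C = train.n_classes
    if d <= M - C:
        raise RegimeError(
            f"d={d} <= M-C={M - C}: no null space; CLDA requires d > M-C"
        )
    return _range_basis(_centered_rows(train.X, train.y), rank_tol)


def common_vector(x: np.ndarray, basis: ScatterBasis) -> np.ndarray:
    """Project one sample onto null(S_W): x_com = x - Q Q^T x."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != basis.Q.shape[0]:
        raise SchemaError(
            f"vector has {x.shape[0]} entries, basis is {basis.Q.shape[0]}-dimensional"
        )
    return x - basis.Q @ (basis.Q.T @ x)


def fit(train: SpectralDataset, **kwargs) -> CommonVectorsLDA:
    """Fit CLDA on a training dataset."""
    return CommonVectorsLDA(**kwargs).fit(train.X, train.y)


def project(model: CommonVectorsLDA, ds: SpectralDataset) -> np.ndarray:
    """Row-wise W^T x for every spectrum in ``ds``."""
    return model.transform(ds.X)


def classify_nearest_common_vector(model: CommonVectorsLDA,
                                   ds: SpectralDataset) -> np.ndarray:
    """Assign each spectrum to the class with the nearest Omega_i."""
    return model.predict(ds.X)
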