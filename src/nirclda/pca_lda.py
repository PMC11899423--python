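"""PCA + LDA baseline: PCA compression followed by Fisher discriminants.

The classical answer to the small-sample problem is a dual-stage
pipeline: compress the centered spectra to k principal components (making
the within-class scatter invertible), then solve the generalized
eigenproblem S_B w = lambda S_W w in the compressed space and keep the
leading (at most C-1) Fisher directions.  This is the comparison method
CLDA is measured against.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .clda import between_class_scatter, within_class_scatter
from .dataset import SpectralDataset
from .exceptions import FitError, ParameterError, SchemaError

__all__ = ["PCALDA", "fit_pca_lda", "project_pca_lda"]


class PCALDA(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Two-stage PCA + Fisher LDA feature extractor and nearest-centroid
    classifier.

    Parameters
    ----------
    n_components : int or "auto"
        Number of principal components kept before LDA.  "auto" keeps the
        smallest k explaining at least ``var_target`` of the training
        variance, capped at M - C so the within-class scatter stays
        invertible in PCA space.
    var_target : float
        Variance fraction for the "auto" rule (default 0.99).
    ridge : float
        Relative Tikhonov stabilizer added to the within-class scatter in
        PCA space when it is numerically singular
        (``ridge * trace(S_W) / k`` on the diagonal).

    Attributes
    ----------
    pca_mean_ : ndarray (d,)
    pca_components_ : ndarray (d, k), orthonormal columns
    lda_scalings_ : ndarray (k, q), q <= C-1 Fisher directions
    fisher_ratios_ : ndarray (q,), generalized eigenvalues (descending)
    class_centroids_ : ndarray (C, q), projected training class means
    """

    def __init__(self, n_components="auto", var_target: float = 0.99,
                 ridge: float = 1e-10):
        self.n_components = n_components
        self.var_target = var_target
        self.ridge = ridge

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        M, d = X.shape
        classes = np.unique(y)
        C = classes.shape[0]
        if C < 2:
            raise ParameterError("need at least 2 classes")
        self.classes_ = classes
        self.pca_mean_ = X.mean(axis=0)
        Xc = X - self.pca_mean_
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(S > S[0] * max(M, d) * np.finfo(float).eps)) if S.size else 0
        if self.n_components == "auto":
            var = S[:rank] ** 2
            cum = np.cumsum(var) / var.sum()
            k = int(np.searchsorted(cum, self.var_target) + 1)
            k = min(k, max(M - C, 1), rank)
        else:
            k = int(self.n_components)
            if not 1 <= k <= M - 1:
                raise ParameterError(f"n_components must be in [1, M-1], got {k}")
            if k > rank:
                raise FitError(
                    f"requested {k} components but training data has rank "
                    f"{rank}; choose a smaller k"
                )
        self.pca_components_ = Vt[:k].T
        self.n_pca_components_ = k
        Z = Xc @ self.pca_components_

        Sw = within_class_scatter(Z, y)
        Sb = between_class_scatter(Z, y)
        w_evals = np.linalg.eigvalsh(Sw)
        if w_evals[0] <= w_evals[-1] * k * np.finfo(float).eps:
            if np.trace(Sw) <= 0:
                raise FitError(
                    "within-class scatter in PCA space is zero; choose a "
                    "smaller number of components"
                )
            Sw = Sw + (self.ridge * np.trace(Sw) / k) * np.eye(k)
        evals, evecs = eigh(Sb, Sw)
        order = np.argsort(evals)[::-1]
        q = min(C - 1, k)
        order = order[:q]
        ratios = evals[order]
        pos = ratios > max(ratios[0], 0) * 1e-12
        order, ratios = order[pos], ratios[pos]
        Wl = evecs[:, order]
        Wl = Wl / np.linalg.norm(Wl, axis=0, keepdims=True)
        for j in range(Wl.shape[1]):
            i = int(np.argmax(np.abs(Wl[:, j])))
            if Wl[i, j] < 0:
                Wl[:, j] = -Wl[:, j]
        self.lda_scalings_ = Wl
        self.fisher_ratios_ = ratios
        self.n_components_ = Wl.shape[1]
        self.n_features_in_ = d
        F = self.transform(X)
        self.class_centroids_ = np.vstack(
            [F[y == c].mean(axis=0) for c in classes]
        )
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"{X.shape[1]} channels, model fitted with {self.n_features_in_}"
            )
        return (X - self.pca_mean_) @ self.pca_components_ @ self.lda_scalings_

    def predict(self, X) -> np.ndarray:
        """Nearest projected class centroid (ties to the lowest class index)."""
        D = cdist(self.transform(X), self.class_centroids_)
        return self.classes_[np.argmin(D, axis=1)]


def fit_pca_lda(train: SpectralDataset, k="auto", **kwargs) -> PCALDA:
    """Fit the PCA + LDA baseline on a training dataset."""
    return PCALDA(n_components=k, **kwargs).fit(train.X, train.y)


def project_pca_lda(model: PCALDA, ds: SpectralDataset) -> np.ndarray:
    """Map spectra through PCA then LDA to the discriminant coordinates."""
    return model.transform(ds.X)
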