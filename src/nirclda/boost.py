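"""AdaBoost-CLDA: an AdaBoost.M1 ensemble of CLDA subspace classifiers.

Each boosting round resamples the training set according to the current
weight distribution, fits CLDA on the resampled subset, and uses the
nearest-neighbour rule in that round's discriminant subspace as the weak
classifier (for CLDA this is exactly the nearest-Omega rule, by the
exact-projection identity).  The weighted error

    eps_t = sum_i P_t(i) * 1[y_i != h_t(x_i)]

is evaluated on the full training set; the round weight is
``alpha_t = 1/2 ln[(1 - eps_t)/eps_t]`` and the sample weights are
multiplied by ``exp(+-alpha_t)`` (up for mistakes, down for hits), which
makes the misclassified samples carry exactly half of the next round's
distribution.  The loop stops early when a round is perfect (eps = 0) or
no better than chance (eps >= 1/2).  The final hypothesis is the
alpha-weighted plurality vote over the retained rounds.

Resampling (rather than weighting CLDA's scatter matrices internally) is
what makes boosting meaningful here: fitted on the full set, CLDA projects
every training sample exactly onto its class template and would report
eps = 0 every round.  Bootstrap subsets give each round a different
null-space geometry, and the vote aggregates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clda import CommonVectorsLDA
from .dataset import SpectralDataset
from .exceptions import FitError, ParameterError, SchemaError

__all__ = ["BoostRound", "AdaBoostCLDA", "fit_adaboost_clda", "predict",
           "staged_accuracy"]


@dataclass
class BoostRound:
    """One retained boosting round: fitted CLDA, its weight and bookkeeping."""

    estimator: CommonVectorsLDA
    alpha: float
    weighted_error: float
    subset_indices: np.ndarray = field(repr=False)


class AdaBoostCLDA:
    """AdaBoost.M1 over resampled CLDA + nearest-Omega weak classifiers.

    Parameters
    ----------
    n_rounds : int
        Requested number of boosting iterations T (default 10, the point
        where the ensemble's accuracy curve flattens on this problem).
    random_state : int, optional
        Seed controlling all resampling.
    max_redraws : int
        A bootstrap draw must contain every class; up to this many redraws
        are attempted before the missing classes are topped up with their
        highest-weight sample.

    Attributes
    ----------
    rounds_ : list of BoostRound
    n_rounds_effective_ : int
    classes_ : ndarray (C,)
    """

    def __init__(self, n_rounds: int = 10, random_state: int | None = None,
                 max_redraws: int = 10):
        self.n_rounds = n_rounds
        self.random_state = random_state
        self.max_redraws = max_redraws

    def get_params(self, deep: bool = True) -> dict:
        return {"n_rounds": self.n_rounds, "random_state": self.random_state,
                "max_redraws": self.max_redraws}

    def set_params(self, **params) -> "AdaBoostCLDA":
        for k, v in params.items():
            if k not in self.get_params():
                raise ParameterError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------
    def _draw_subset(self, rng, n: int, P: np.ndarray, y_idx: np.ndarray,
                     n_classes: int) -> np.ndarray:
        for _ in range(self.max_redraws + 1):
            idx = rng.choice(n, size=n, replace=True, p=P)
            if np.unique(y_idx[idx]).size == n_classes:
                return idx
        # top up: add each missing class's highest-weight sample
        present = np.unique(y_idx[idx])
        extras = []
        for c in range(n_classes):
            if c not in present:
                members = np.flatnonzero(y_idx == c)
                extras.append(members[np.argmax(P[members])])
        return np.concatenate([idx, np.asarray(extras, dtype=idx.dtype)])

    def fit(self, X, y) -> "AdaBoostCLDA":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        n = X.shape[0]
        if y.shape[0] != n:
            raise SchemaError(f"{y.shape[0]} labels for {n} samples")
        T = int(self.n_rounds)
        if T < 1:
            raise ParameterError(f"n_rounds must be >= 1, got {T}")
        classes = np.unique(y)
        C = classes.shape[0]
        y_idx = np.searchsorted(classes, y)
        rng = np.random.default_rng(self.random_state)

        w = np.full(n, 1.0 / n)
        rounds: list[BoostRound] = []
        for t in range(T):
            P = w / w.sum()
            idx = self._draw_subset(rng, n, P, y_idx, C)
            weak = CommonVectorsLDA().fit(X[idx], y[idx])
            h = weak.predict(X)
            miss = h != y
            eps = float(P[miss].sum())
            if eps == 0.0:
                # a perfect round: retain it with a capped weight, then stop
                eps_min = 1.0 / (2.0 * n)
                alpha = 0.5 * np.log((1.0 - eps_min) / eps_min)
                rounds.append(BoostRound(weak, float(alpha), eps, idx))
                break
            if eps >= 0.5:
                # no better than chance: terminate without retaining
                if not rounds:
                    raise FitError(
                        f"first boosting round has weighted error "
                        f"{eps:.3f} >= 0.5; the weak learner is no better "
                        "than chance — consider preprocessing the spectra"
                    )
                break
            alpha = 0.5 * np.log((1.0 - eps) / eps)
            rounds.append(BoostRound(weak, float(alpha), eps, idx))
            # Eq-style update: Z_t = sum_i P_t(i) = 1 for a normalized
            # distribution, so this alone does not renormalize; the next
            # round's step (1) does.
            w = P * np.exp(np.where(miss, alpha, -alpha))

        self.classes_ = classes
        self.rounds_ = rounds
        self.n_rounds_requested_ = T
        self.n_rounds_effective_ = len(rounds)
        self.n_features_in_ = X.shape[1]
        return self

    # -- prediction --------------------------------------------------------
    def _check_fitted(self) -> None:
        if not getattr(self, "rounds_", None):
            raise FitError("model has no fitted rounds")

    def _vote_matrix(self, X, n_rounds: int | None = None) -> np.ndarray:
        """Cumulative alpha-weighted votes, shape (n_samples, C)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        upto = self.n_rounds_effective_ if n_rounds is None else n_rounds
        votes = np.zeros((X.shape[0], self.classes_.shape[0]))
        for rnd in self.rounds_[:upto]:
            h = rnd.estimator.predict(X)
            votes[np.arange(X.shape[0]),
                  np.searchsorted(self.classes_, h)] += rnd.alpha
        return votes

    def predict(self, X) -> np.ndarray:
        """argmax_y sum_t alpha_t 1[h_t(x) = y]; ties to the lowest class index."""
        votes = self._vote_matrix(X)
        return self.classes_[np.argmax(votes, axis=1)]

    def staged_accuracy(self, X, y_true) -> np.ndarray:
        """Accuracy of the vote truncated to the first t rounds, t = 1..T_eff."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y_true = np.asarray(y_true)
        if y_true.shape[0] != X.shape[0]:
            raise SchemaError(
                f"{y_true.shape[0]} labels for {X.shape[0]} samples"
            )
        votes = np.zeros((X.shape[0], self.classes_.shape[0]))
        out = np.empty(self.n_rounds_effective_)
        for t, rnd in enumerate(self.rounds_):
            h = rnd.estimator.predict(X)
            votes[np.arange(X.shape[0]),
                  np.searchsorted(self.classes_, h)] += rnd.alpha
            pred = self.classes_[np.argmax(votes, axis=1)]
            out[t] = float(np.mean(pred == y_true))
        return out

    @property
    def alphas_(self) -> np.ndarray:
        return np.array([r.alpha for r in self.rounds_])

    @property
    def weighted_errors_(self) -> np.ndarray:
        return np.array([r.weighted_error for r in self.rounds_])


# -- spec-surface wrappers -------------------------------------------------

def fit_adaboost_clda(train: SpectralDataset, T: int = 10,
                      seed: int | None = None) -> AdaBoostCLDA:
    """Fit the boosted CLDA ensemble on a training dataset."""
    return AdaBoostCLDA(n_rounds=T, random_state=seed).fit(train.X, train.y)


def predict(model: AdaBoostCLDA, ds: SpectralDataset) -> np.ndarray:
    """Alpha-weighted ensemble vote for every spectrum."""
    return model.predict(ds.X)


def staged_accuracy(model: AdaBoostCLDA, ds: SpectralDataset,
                    truth: np.ndarray) -> np.ndarray:
    """Per-iteration accuracy curve of the truncated vote."""
    return model.staged_accuracy(ds.X, truth)
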