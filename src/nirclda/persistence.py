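"""Model archives: save/load fitted extractors for train/predict separation.

A single ``.npz`` archive per model, with a ``kind`` tag and a JSON
metadata blob; boosted ensembles store one array group per round.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .boost import AdaBoostCLDA, BoostRound
from .clda import CommonVectorsLDA, ScatterBasis
from .exceptions import ConfigError
from .pca_lda import PCALDA

__all__ = ["save_model", "load_model"]


def _clda_arrays(model: CommonVectorsLDA, prefix: str = "") -> dict:
    return {
        f"{prefix}Q": model.basis_.Q,
        f"{prefix}basis_eigenvalues": model.basis_.eigenvalues,
        f"{prefix}common_vectors": model.common_vectors_,
        f"{prefix}mu_com": model.mu_com_,
        f"{prefix}scalings": model.scalings_,
        f"{prefix}omegas": model.omegas_,
        f"{prefix}classes": model.classes_.astype(str),
    }


def _clda_from(arrays, prefix: str = "") -> CommonVectorsLDA:
    model = CommonVectorsLDA()
    Q = arrays[f"{prefix}Q"]
    model.basis_ = ScatterBasis(Q=Q, rank=Q.shape[1],
                                eigenvalues=arrays[f"{prefix}basis_eigenvalues"])
    model.common_vectors_ = arrays[f"{prefix}common_vectors"]
    model.mu_com_ = arrays[f"{prefix}mu_com"]
    model.scalings_ = arrays[f"{prefix}scalings"]
    model.omegas_ = arrays[f"{prefix}omegas"]
    model.classes_ = arrays[f"{prefix}classes"].astype(str)
    model.n_features_in_ = model.scalings_.shape[0]
    model.n_components_ = model.scalings_.shape[1]
    return model


def save_model(model, path) -> Path:
    path = Path(path)
    if isinstance(model, CommonVectorsLDA):
        np.savez(path, kind="clda", **_clda_arrays(model))
    elif isinstance(model, PCALDA):
        np.savez(path, kind="pca_lda",
                 pca_mean=model.pca_mean_,
                 pca_components=model.pca_components_,
                 lda_scalings=model.lda_scalings_,
                 fisher_ratios=model.fisher_ratios_,
                 class_centroids=model.class_centroids_,
                 classes=model.classes_.astype(str))
    elif isinstance(model, AdaBoostCLDA):
        arrays = {"kind": "adaboost_clda",
                  "classes": model.classes_.astype(str),
                  "alphas": model.alphas_,
                  "weighted_errors": model.weighted_errors_,
                  "meta": json.dumps({
                      "n_rounds_requested": model.n_rounds_requested_,
                      "n_rounds_effective": model.n_rounds_effective_,
                      "random_state": model.random_state,
                  })}
        for t, rnd in enumerate(model.rounds_):
            arrays.update(_clda_arrays(rnd.estimator, prefix=f"r{t}_"))
            arrays[f"r{t}_subset"] = rnd.subset_indices
        np.savez(path, **arrays)
    else:
        raise ConfigError(f"cannot archive a {type(model).__name__}")
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path):
    with np.load(Path(path), allow_pickle=False) as data:
        arrays = {k: data[k] for k in data.files}
    kind = str(arrays.pop("kind"))
    if kind == "clda":
        return _clda_from(arrays)
    if kind == "pca_lda":
        model = PCALDA()
        model.pca_mean_ = arrays["pca_mean"]
        model.pca_components_ = arrays["pca_components"]
        model.lda_scalings_ = arrays["lda_scalings"]
        model.fisher_ratios_ = arrays["fisher_ratios"]
        model.class_centroids_ = arrays["class_centroids"]
        model.classes_ = arrays["classes"].astype(str)
        model.n_features_in_ = model.pca_mean_.shape[0]
        model.n_pca_components_ = model.pca_components_.shape[1]
        model.n_components_ = model.lda_scalings_.shape[1]
        return model
    if kind == "adaboost_clda":
        meta = json.loads(str(arrays["meta"]))
        model = AdaBoostCLDA(n_rounds=meta["n_rounds_requested"],
                             random_state=meta["random_state"])
        model.classes_ = arrays["classes"].astype(str)
        alphas = arrays["alphas"]
        errors = arrays["weighted_errors"]
        model.rounds_ = [
            BoostRound(estimator=_clda_from(arrays, prefix=f"r{t}_"),
                       alpha=float(alphas[t]),
                       weighted_error=float(errors[t]),
                       subset_indices=arrays[f"r{t}_subset"])
            for t in range(meta["n_rounds_effective"])
        ]
        model.n_rounds_requested_ = meta["n_rounds_requested"]
        model.n_rounds_effective_ = meta["n_rounds_effective"]
        model.n_features_in_ = (model.rounds_[0].estimator.n_features_in_
                                if model.rounds_ else 0)
        return model
    raise ConfigError(f"unknown model kind {kind!r} in {path}")
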