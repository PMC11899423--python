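"""End-to-end experiment drivers: preprocess -> extract -> classify -> score.

`run_experiment` executes one configuration on a dataset (internally doing
the stratified split); `run_grid` sweeps preprocessing recipes x extractors
x classifiers, mirroring the accuracy-table experiment design; `k_sweep`
traces accuracy against the KNN neighbourhood size.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boost, clda, pca_lda
from .classifiers import GaussianNaiveBayes, KNNClassifier, ConfusionMatrix, evaluate
from .dataset import SpectralDataset, stratified_split
from .exceptions import ConfigError, NirCldaError
from .preprocess import PreprocessSpec, apply_chain

__all__ = ["RunConfig", "ExperimentReport", "run_experiment", "run_grid",
           "k_sweep", "grid_table"]

EXTRACTORS = ("pca_lda", "clda", "adaboost_clda")
CLASSIFIERS = ("nearest_common_vector", "knn", "bayes")


@dataclass
class RunConfig:
    """One pipeline configuration.

    ``classifier='nearest_common_vector'`` means the extractor's native
    rule: nearest Omega for CLDA, nearest projected centroid for PCA+LDA,
    and the alpha-weighted ensemble vote for AdaBoost-CLDA.
    """

    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    extractor: str = "clda"
    classifier: str = "nearest_common_vector"
    knn_k: int = 7
    boost_T: int = 10
    split_ratio: tuple[int, int] = (2, 1)
    seed: int = 0

    def __post_init__(self):
        if self.extractor not in EXTRACTORS:
            raise ConfigError(f"unknown extractor {self.extractor!r}")
        if self.classifier not in CLASSIFIERS:
            raise ConfigError(f"unknown classifier {self.classifier!r}")

    def to_dict(self) -> dict:
        return {
            "preprocess": self.preprocess.to_dict(),
            "extractor": self.extractor,
            "classifier": self.classifier,
            "knn_k": self.knn_k,
            "boost_T": self.boost_T,
            "split_ratio": list(self.split_ratio),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        pp = data.pop("preprocess", {"steps": []})
        ratio = tuple(data.pop("split_ratio", (2, 1)))
        return cls(preprocess=PreprocessSpec.from_dict(pp),
                   split_ratio=ratio, **data)


@dataclass
class ExperimentReport:
    """Outcome of one `run_experiment` call."""

    accuracy: float
    confusion: ConfusionMatrix
    config: RunConfig
    predictions: np.ndarray
    truth: np.ndarray
    staged_accuracy: np.ndarray | None = None
    n_rounds_effective: int | None = None


def _back_classifier(cfg: RunConfig):
    if cfg.classifier == "knn":
        return KNNClassifier(k=cfg.knn_k)
    return GaussianNaiveBayes()


def _extract_and_classify(train: SpectralDataset, test: SpectralDataset,
                          cfg: RunConfig):
    """Returns (predictions, staged, n_rounds_effective)."""
    if cfg.extractor == "clda":
        model = clda.fit(train)
        if cfg.classifier == "nearest_common_vector":
            return model.predict(test.X), None, None
        clf = _back_classifier(cfg).fit(model.transform(train.X), train.y)
        return clf.predict(model.transform(test.X)), None, None

    if cfg.extractor == "pca_lda":
        model = pca_lda.fit_pca_lda(train)
        if cfg.classifier == "nearest_common_vector":
            return model.predict(test.X), None, None
        clf = _back_classifier(cfg).fit(model.transform(train.X), train.y)
        return clf.predict(model.transform(test.X)), None, None

    # adaboost_clda
    model = boost.fit_adaboost_clda(train, T=cfg.boost_T, seed=cfg.seed)
    staged = model.staged_accuracy(test.X, test.y)
    if cfg.classifier == "nearest_common_vector":
        return model.predict(test.X), staged, model.n_rounds_effective_
    # back-end classifier per round, combined by the same alpha vote: each
    # round's subspace gets a KNN/NB trained on the full projected training
    # set, and rounds vote with their boosting weights
    votes = np.zeros((test.n_samples, model.classes_.shape[0]))
    for rnd in model.rounds_:
        ft_train = rnd.estimator.transform(train.X)
        ft_test = rnd.estimator.transform(test.X)
        clf = _back_classifier(cfg).fit(ft_train, train.y)
        h = clf.predict(ft_test)
        votes[np.arange(test.n_samples),
              np.searchsorted(model.classes_, h)] += rnd.alpha
    pred = model.classes_[np.argmax(votes, axis=1)]
    return pred, staged, model.n_rounds_effective_


def run_experiment(data: SpectralDataset, cfg: RunConfig,
                   verbose: bool = False) -> ExperimentReport:
    """Split, preprocess, extract, classify and score one configuration."""
    split = stratified_split(data, cfg.split_ratio, cfg.seed)
    train, test = apply_chain(split.train, split.test, cfg.preprocess)
    if verbose:
        print(f"[run] preprocess={cfg.preprocess.name} extractor={cfg.extractor} "
              f"classifier={cfg.classifier} seed={cfg.seed} "
              f"train={train.n_samples} test={test.n_samples}", file=sys.stderr)
    pred, staged, t_eff = _extract_and_classify(train, test, cfg)
    acc, cm = evaluate(pred, test.y, class_order=data.classes)
    return ExperimentReport(accuracy=acc, confusion=cm, config=cfg,
                            predictions=pred, truth=test.y,
                            staged_accuracy=staged, n_rounds_effective=t_eff)


def run_grid(data: SpectralDataset,
             preprocess_grid: list[PreprocessSpec],
             extractors: list[str] = list(EXTRACTORS),
             classifiers: list[str] = ["knn"],
             cfg: RunConfig | None = None,
             verbose: bool = False) -> pd.DataFrame:
    """Accuracy for every (preprocess, extractor, classifier) cell.

    Cells are independent; a failing cell is recorded with its error message
    and the grid continues.  Returns a long-format DataFrame with columns
    preprocess, extractor, classifier, accuracy, error.
    """
    if not preprocess_grid or not extractors or not classifiers:
        raise ConfigError("empty grid axis")
    base = cfg if cfg is not None else RunConfig()
    rows = []
    for pp in preprocess_grid:
        for ex in extractors:
            for cl in classifiers:
                cell_cfg = RunConfig(
                    preprocess=pp, extractor=ex, classifier=cl,
                    knn_k=base.knn_k, boost_T=base.boost_T,
                    split_ratio=base.split_ratio, seed=base.seed,
                )
                try:
                    rep = run_experiment(data, cell_cfg, verbose=verbose)
                    rows.append({"preprocess": pp.name, "extractor": ex,
                                 "classifier": cl, "accuracy": rep.accuracy,
                                 "error": None})
                except NirCldaError as exc:
                    rows.append({"preprocess": pp.name, "extractor": ex,
                                 "classifier": cl, "accuracy": np.nan,
                                 "error": f"{ex}/{pp.name}: {exc}"})
    return pd.DataFrame(rows)


def grid_table(grid: pd.DataFrame, classifier: str = "knn") -> pd.DataFrame:
    """Pivot a grid to the accuracy-table layout: rows = extractor,
    columns = preprocessing recipe."""
    sub = grid[grid["classifier"] == classifier]
    return sub.pivot(index="extractor", columns="preprocess", values="accuracy")


def k_sweep(data: SpectralDataset, cfg: RunConfig | None = None,
            ks=range(1, 16),
            extractors: list[str] = list(EXTRACTORS)) -> pd.DataFrame:
    """Test accuracy against the KNN neighbourhood size for each extractor."""
    base = cfg if cfg is not None else RunConfig()
    rows = []
    for ex in extractors:
        for k in ks:
            cell = RunConfig(preprocess=base.preprocess, extractor=ex,
                             classifier="knn", knn_k=int(k),
                             boost_T=base.boost_T,
                             split_ratio=base.split_ratio, seed=base.seed)
            rep = run_experiment(data, cell)
            rows.append({"extractor": ex, "k": int(k),
                         "accuracy": rep.accuracy})
    return pd.DataFrame(rows)
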