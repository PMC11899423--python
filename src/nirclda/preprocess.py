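"""Spectral preprocessing: Savitzky-Golay filtering, MSC and SNV.

Each operator is a scikit-learn style transformer working on an
``(n_samples, n_channels)`` matrix, plus a thin dataset-level function.
Ordered combinations ("MSC + SG" etc.) are described by a
:class:`PreprocessSpec` and applied with :func:`apply_chain`; any statistic
a step learns from data (the MSC mean reference) is computed on the
training set only and frozen for the test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectralDataset
from .exceptions import ConfigError, DegenerateDataError, ParameterError

__all__ = [
    "SavitzkyGolay",
    "MultiplicativeScatterCorrection",
    "StandardNormalVariate",
    "PreprocessSpec",
    "sg_filter",
    "msc",
    "snv",
    "apply_chain",
]


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Savitzky-Golay local polynomial smoothing (or derivative) per spectrum.

    Each spectrum is replaced by its local least-squares polynomial fit of
    degree ``poly_order`` over a sliding window of ``window_length``
    channels.  Edges are handled by evaluating the edge polynomials
    (scipy's ``mode='interp'``) so the channel count is preserved.

    Defaults (window 11, order 2, derivative 0) are common NIR smoothing
    practice; the filter reproduces polynomials up to its order exactly,
    and with ``poly_order = window_length - 1`` it is the identity.
    """

    def __init__(self, window_length: int = 11, poly_order: int = 2,
                 derivative: int = 0):
        self.window_length = window_length
        self.poly_order = poly_order
        self.derivative = derivative

    def _validate(self, d: int) -> None:
        w, p, dv = self.window_length, self.poly_order, self.derivative
        if w % 2 == 0 or w < 3:
            raise ParameterError(f"window_length must be odd and >= 3, got {w}")
        if w > d:
            raise ParameterError(f"window_length {w} exceeds {d} channels")
        if not 0 <= p < w:
            raise ParameterError(
                f"poly_order must satisfy 0 <= poly_order < window_length, "
                f"got {p} with window {w}"
            )
        if not 0 <= dv <= p:
            raise ParameterError(
                f"derivative must satisfy 0 <= derivative <= poly_order, got {dv}"
            )

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._validate(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._validate(X.shape[1])
        return savgol_filter(X, self.window_length, self.poly_order,
                             deriv=self.derivative, axis=-1, mode="interp")


class MultiplicativeScatterCorrection(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x`` is regressed on the reference ``r`` by ordinary
    least squares, ``x ≈ a*r + b``, and replaced by ``(x - b) / a``, which
    removes per-spectrum multiplicative and additive scatter.  With
    ``reference='mean'`` the reference is the mean of the spectra seen at
    ``fit`` time (the training set), frozen for later transforms.
    """

    def __init__(self, reference="mean"):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if isinstance(self.reference, str):
            if self.reference != "mean":
                raise ConfigError(f"unknown MSC reference {self.reference!r}")
            ref = X.mean(axis=0)
        else:
            ref = np.asarray(self.reference, dtype=float).ravel()
            if ref.shape[0] != X.shape[1]:
                raise ConfigError(
                    f"reference length {ref.shape[0]} != {X.shape[1]} channels"
                )
        centered = ref - ref.mean()
        sxx = float(centered @ centered)
        if sxx <= 1e-300:
            raise DegenerateDataError("MSC reference spectrum is constant")
        self.reference_ = ref
        self._centered_ref = centered
        self._sxx = sxx
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.reference_.shape[0]:
            raise ConfigError(
                f"{X.shape[1]} channels, reference has {self.reference_.shape[0]}"
            )
        row_mean = X.mean(axis=1)
        a = (X - row_mean[:, None]) @ self._centered_ref / self._sxx
        bad = np.abs(a) < 1e-12
        if bad.any():
            raise DegenerateDataError(
                f"MSC fit degenerate (|slope| < 1e-12) for sample(s) "
                f"{np.flatnonzero(bad).tolist()}"
            )
        b = row_mean - a * self.reference_.mean()
        return (X - b[:, None]) / a[:, None]


class StandardNormalVariate(TransformerMixin, BaseEstimator):
    """Standard normal variate: centre and scale each spectrum on its own.

    Every spectrum is independently transformed to mean 0 and sample
    standard deviation 1 (divisor d-1).  Stateless, idempotent, and
    invariant to per-spectrum positive affine distortion.
    """

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        flat = sd.ravel() == 0
        if flat.any():
            raise DegenerateDataError(
                f"constant spectrum (zero sd) at sample(s) "
                f"{np.flatnonzero(flat).tolist()}"
            )
        return (X - mean) / sd


_METHODS = {
    "SG": SavitzkyGolay,
    "MSC": MultiplicativeScatterCorrection,
    "SNV": StandardNormalVariate,
}

# YAML/CLI aliases for step parameters
_PARAM_ALIASES = {"window": "window_length", "order": "poly_order",
                  "deriv": "derivative"}


@dataclass
class PreprocessSpec:
    """Ordered preprocessing recipe: list of (method, params) steps.

    ``steps=[]`` means raw spectra.  Serializable to/from a YAML/JSON
    block such as::

        steps:
          - {method: MSC, reference: mean}
          - {method: SG, window: 11, order: 2}
    """

    steps: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self):
        norm = []
        for step in self.steps:
            method, params = step
            method = str(method).upper()
            if method not in _METHODS:
                raise ConfigError(f"unknown preprocessing method {method!r}")
            params = {
                _PARAM_ALIASES.get(k, k): v for k, v in dict(params).items()
            }
            norm.append((method, params))
        self.steps = norm

    @property
    def name(self) -> str:
        return " + ".join(m for m, _ in self.steps) if self.steps else "raw"

    def make_transformers(self):
        return [_METHODS[m](**p) for m, p in self.steps]

    def to_dict(self) -> dict:
        return {"steps": [{"method": m, **p} for m, p in self.steps]}

    @classmethod
    def from_dict(cls, data: dict) -> "PreprocessSpec":
        steps = []
        for entry in data.get("steps", []):
            entry = dict(entry)
            method = entry.pop("method", None)
            if method is None:
                raise ConfigError(f"preprocessing step without method: {entry}")
            steps.append((method, entry))
        return cls(steps=steps)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PreprocessSpec":
        return cls.from_dict(yaml.safe_load(text) or {})


# -- dataset-level wrappers ------------------------------------------------

def sg_filter(ds: SpectralDataset, window_length: int = 11,
              poly_order: int = 2, derivative: int = 0) -> SpectralDataset:
    tf = SavitzkyGolay(window_length, poly_order, derivative)
    return ds.with_absorbance(tf.fit(ds.X).transform(ds.X))


def msc(ds: SpectralDataset, reference="mean") -> SpectralDataset:
    tf = MultiplicativeScatterCorrection(reference)
    return ds.with_absorbance(tf.fit(ds.X).transform(ds.X))


def snv(ds: SpectralDataset) -> SpectralDataset:
    return ds.with_absorbance(StandardNormalVariate().fit(ds.X).transform(ds.X))


def apply_chain(ds_train: SpectralDataset, ds_test: SpectralDataset | None,
                spec: PreprocessSpec):
    """Apply an ordered preprocessing recipe, fitting on train only.

    Steps run left-to-right; every step is fitted on the (current) training
    matrix and then applied to both sets, so training-derived statistics
    (the MSC mean reference) never leak from the test set.
    """
    Xtr = ds_train.X
    Xte = None if ds_test is None else ds_test.X
    for tf in spec.make_transformers():
        tf.fit(Xtr)
        Xtr = tf.transform(Xtr)
        if Xte is not None:
            Xte = tf.transform(Xte)
    out_train = ds_train.with_absorbance(Xtr)
    out_test = None if ds_test is None else ds_test.with_absorbance(Xte)
    return out_train, out_test
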