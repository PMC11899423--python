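"""Synthetic origin-labelled NIR spectra generator.

Emulates the statistical structure of diffuse-reflectance NIR absorbance
spectra of a fruit scanned on a portable spectrometer: a smooth mixture of
Gaussian absorption bands on a sloped baseline, shared band positions
across origins (two prominent bands near 8475 and 6993 cm^-1) with
origin-dependent band *amplitudes*, per-spectrum multiplicative/additive
scatter, and i.i.d. channel noise:

    x = a_s * (sum_k amp_{class,k} * G(axis; center_k, width_k) + baseline)
        + b_s + eps,      a_s ~ N(1, sigma_a),  b_s ~ N(0, sigma_b),
                          eps ~ N(0, noise_sd^2) per channel.

The default spec reproduces the study conditions the rest of the package
assumes: 4 origin classes x 60 samples, 228 channels spanning
5894.5-11111 cm^-1 (900-1700 nm).  ``class_separation`` scales the
between-class amplitude differences around their across-class mean, so 0
makes all classes identically distributed (chance regime) and larger
values pull them apart.

What this generator does *not* model: real overtone/combination band
physics, instrument line shape and wavelength-dependent noise, or
within-origin biological covariance structure.  Conclusions drawn on it
are about the algorithms, not about jujubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import SpectralDataset
from .exceptions import ConfigError

__all__ = ["SyntheticSpec", "default_peaks", "generate", "preset"]

AXIS_RANGE = (5894.5, 11111.0)

# (center cm^-1, base amplitude, width cm^-1): two prominent bands at 6993
# and 8475 plus two weaker flanking bands for realistic overlap
_BASE_BANDS = [
    (6993.0, 0.80, 330.0),
    (8475.0, 0.55, 420.0),
    (6150.0, 0.40, 300.0),
    (10150.0, 0.25, 520.0),
]

# relative amplitude offsets per (class, band); rows are the four origins
_CLASS_REL = np.array([
    [+0.060, -0.030, +0.020, -0.050],
    [-0.045, +0.055, -0.035, +0.025],
    [+0.020, +0.025, -0.060, +0.050],
    [-0.035, -0.050, +0.055, -0.025],
])

_DEFAULT_LABELS = ["gansu", "henan", "shanxi", "xinjiang"]


def default_peaks(n_classes: int = 4) -> list[list[tuple[float, float, float]]]:
    """Per-class (center, amplitude, width) band lists with class-dependent
    amplitudes around the shared base bands."""
    if n_classes <= _CLASS_REL.shape[0]:
        rel = _CLASS_REL[:n_classes]
    else:
        extra = np.random.default_rng(20240512).uniform(
            -0.06, 0.06, size=(n_classes - _CLASS_REL.shape[0],
                               _CLASS_REL.shape[1]))
        rel = np.vstack([_CLASS_REL, extra])
    return [
        [(c, a * (1.0 + rel[i, k]), w)
         for k, (c, a, w) in enumerate(_BASE_BANDS)]
        for i in range(n_classes)
    ]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic spectra generator (see module docstring)."""

    n_classes: int = 4
    samples_per_class: int = 60
    n_channels: int = 228
    axis_range: tuple[float, float] = AXIS_RANGE
    peaks: list | None = None  # per-class [(center, amplitude, width), ...]
    baseline: tuple[float, float] = (0.25, 8e-6)  # offset, slope per cm^-1
    scatter_sd: tuple[float, float] = (0.05, 0.02)  # sigma_a, sigma_b
    noise_sd: float = 0.005
    class_separation: float = 1.0
    seed: int = 0

    def resolved_peaks(self) -> list:
        return self.peaks if self.peaks is not None else default_peaks(self.n_classes)

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if self.samples_per_class < 1 or self.n_channels < 2:
            raise ConfigError("invalid sample or channel count")
        lo, hi = self.axis_range
        if not lo < hi:
            raise ConfigError(f"empty axis range {self.axis_range}")
        pk = self.resolved_peaks()
        if len(pk) != self.n_classes:
            raise ConfigError(
                f"{len(pk)} per-class peak lists for {self.n_classes} classes"
            )
        n_bands = {len(p) for p in pk}
        if len(n_bands) != 1:
            raise ConfigError("every class needs the same number of bands")
        for plist in pk:
            for center, _amp, width in plist:
                if not lo <= center <= hi:
                    raise ConfigError(
                        f"band center {center} outside axis range {self.axis_range}"
                    )
                if width <= 0:
                    raise ConfigError(f"band width must be positive, got {width}")
        if min(self.scatter_sd) < 0 or self.noise_sd < 0:
            raise ConfigError("noise/scatter standard deviations must be >= 0")
        if self.class_separation < 0:
            raise ConfigError("class_separation must be >= 0")


def _labels_for(n_classes: int) -> list[str]:
    if n_classes == len(_DEFAULT_LABELS):
        return list(_DEFAULT_LABELS)
    return [f"class{i + 1:02d}" for i in range(n_classes)]


def generate(spec: SyntheticSpec) -> SpectralDataset:
    """Draw a fully seed-deterministic synthetic dataset from ``spec``."""
    spec.validate()
    axis = np.linspace(spec.axis_range[0], spec.axis_range[1], spec.n_channels)
    pk = spec.resolved_peaks()
    centers = np.array([[b[0] for b in plist] for plist in pk])
    amps = np.array([[b[1] for b in plist] for plist in pk])
    widths = np.array([[b[2] for b in plist] for plist in pk])
    # scale amplitude differences around the across-class mean
    amp_mean = amps.mean(axis=0)
    amps = amp_mean + spec.class_separation * (amps - amp_mean)

    offset, slope = spec.baseline
    base = offset + slope * (axis - axis[0])
    clean = np.empty((spec.n_classes, spec.n_channels))
    for i in range(spec.n_classes):
        bands = amps[i][:, None] * np.exp(
            -0.5 * ((axis[None, :] - centers[i][:, None]) / widths[i][:, None]) ** 2
        )
        clean[i] = bands.sum(axis=0) + base

    rng = np.random.default_rng(spec.seed)
    sigma_a, sigma_b = spec.scatter_sd
    labels_by_class = _labels_for(spec.n_classes)
    n = spec.n_classes * spec.samples_per_class
    X = np.empty((n, spec.n_channels))
    labels = np.empty(n, dtype=object)
    ids = np.empty(n, dtype=object)
    row = 0
    for i in range(spec.n_classes):
        for m in range(spec.samples_per_class):
            a = rng.normal(1.0, sigma_a) if sigma_a > 0 else 1.0
            b = rng.normal(0.0, sigma_b) if sigma_b > 0 else 0.0
            eps = (rng.normal(0.0, spec.noise_sd, spec.n_channels)
                   if spec.noise_sd > 0 else 0.0)
            X[row] = a * clean[i] + b + eps
            labels[row] = labels_by_class[i]
            ids[row] = f"{labels_by_class[i]}_{m:03d}"
            row += 1
    return SpectralDataset(absorbance=X, axis=axis,
                           labels=labels.astype(str),
                           sample_ids=ids.astype(str), axis_unit="cm-1")


def preset(name: str) -> SyntheticSpec:
    """Named generator regimes used throughout the test suite.

    ``separable``
        Large amplitude separation, little noise/scatter: CLDA alone
        separates the test set perfectly.
    ``overlapping``
        Reduced separation with more noise and scatter — pairs of origins
        become confusable for a single CLDA subspace; the regime where the
        boosted ensemble earns its keep.
    ``scatter_heavy``
        Strong per-spectrum multiplicative/additive scatter; exercises
        MSC/SNV correction.
    """
    if name == "separable":
        return SyntheticSpec(class_separation=2.0, noise_sd=0.002,
                             scatter_sd=(0.01, 0.005))
    if name == "overlapping":
        return SyntheticSpec(class_separation=0.18, noise_sd=0.008,
                             scatter_sd=(0.10, 0.04))
    if name == "scatter_heavy":
        return SyntheticSpec(class_separation=1.0, noise_sd=0.005,
                             scatter_sd=(0.30, 0.15))
    raise ConfigError(f"unknown preset {name!r}")


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    """Copy of ``spec`` with a different seed."""
    return replace(spec, seed=int(seed))
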