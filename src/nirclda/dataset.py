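"""Spectral dataset container, delimited-text I/O and stratified splitting.

The :class:`SpectralDataset` is the currency passed between every stage of
the pipeline: an ``(n_samples, n_channels)`` absorbance matrix, the channel
axis (wavelength in nm or wavenumber in cm^-1 — carried as metadata only,
no algorithm reads it), one categorical origin label per sample and a
sample identifier per row.

Files are plain delimited text (CSV/TSV, autodetected by extension): the
header row holds the numeric axis values, plus a ``label`` column and an
optional ``sample_id`` column.  A long-format reader
(sample_id, wavelength, absorbance, label) is provided for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError, SchemaError

__all__ = [
    "SpectralDataset",
    "SplitResult",
    "read_matrix",
    "read_long",
    "write_matrix",
    "stratified_split",
    "class_mean_spectra",
]


@dataclass
class SpectralDataset:
    """Absorbance matrix with channel axis, class labels and sample ids.

    Parameters
    ----------
    absorbance : ndarray of shape (n_samples, n_channels)
        Unitless absorbance values.
    axis : ndarray of shape (n_channels,)
        Channel positions, strictly monotone (ascending or descending).
    labels : ndarray of shape (n_samples,)
        Categorical class identifiers (stored as strings).
    sample_ids : ndarray of shape (n_samples,), optional
        Unique sample identifiers; generated as ``s0000, s0001, ...`` when
        omitted.
    axis_unit : str
        Unit of ``axis`` ("cm-1" or "nm"); metadata only.
    """

    absorbance: np.ndarray
    axis: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray | None = None
    axis_unit: str = "cm-1"

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.axis = np.asarray(self.axis, dtype=float).ravel()
        self.labels = np.asarray(self.labels, dtype=str).ravel()
        n, d = self.absorbance.shape
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:04d}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=str).ravel()
        if self.labels.shape[0] != n:
            raise SchemaError(
                f"{self.labels.shape[0]} labels for {n} spectra"
            )
        if self.sample_ids.shape[0] != n:
            raise SchemaError(
                f"{self.sample_ids.shape[0]} sample ids for {n} spectra"
            )
        if self.axis.shape[0] != d:
            raise SchemaError(
                f"axis has {self.axis.shape[0]} entries for {d} channels"
            )
        diffs = np.diff(self.axis)
        if d > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise SchemaError("channel axis must be strictly monotone")

    # -- convenience views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique labels; this lexicographic order fixes the internal
        class indexing used everywhere downstream."""
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return self.classes.shape[0]

    @property
    def ascending(self) -> bool:
        return bool(self.axis.shape[0] < 2 or self.axis[1] > self.axis[0])

    @property
    def X(self) -> np.ndarray:
        return self.absorbance

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def select(self, indices: np.ndarray) -> "SpectralDataset":
        """Row subset as a new dataset (axis shared)."""
        idx = np.asarray(indices)
        return SpectralDataset(
            absorbance=self.absorbance[idx],
            axis=self.axis,
            labels=self.labels[idx],
            sample_ids=self.sample_ids[idx],
            axis_unit=self.axis_unit,
        )

    def with_absorbance(self, X: np.ndarray) -> "SpectralDataset":
        """Same metadata with a replaced absorbance matrix (same shape)."""
        X = np.asarray(X, dtype=float)
        if X.shape != self.absorbance.shape:
            raise SchemaError(
                f"replacement shape {X.shape} != {self.absorbance.shape}"
            )
        return SpectralDataset(
            absorbance=X,
            axis=self.axis,
            labels=self.labels,
            sample_ids=self.sample_ids,
            axis_unit=self.axis_unit,
        )


@dataclass
class SplitResult:
    """Outcome of a per-class (stratified) train/test partition."""

    train: SpectralDataset
    test: SpectralDataset
    ratio: tuple[int, int]
    seed: int


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_matrix(path, orientation: str = "samples_in_rows") -> SpectralDataset:
    """Read a delimited-text spectral matrix.

    The header row (or first column for ``samples_in_columns``) carries the
    numeric axis; a ``label`` column is mandatory, ``sample_id`` optional.
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "samples_in_columns"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str,
                         skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # ragged rows with extra fields
        raise ParseError(f"{path.name}: {exc}") from None
    if orientation == "samples_in_columns":
        df = df.T.reset_index(drop=True)
    header = [str(v).strip() for v in df.iloc[0]]
    body = df.iloc[1:].reset_index(drop=True)
    body.columns = header
    if "label" not in header:
        raise SchemaError(f"{path.name}: no 'label' column/row present")
    labels = body["label"].to_numpy(dtype=str)
    if any(lab in ("", "nan") for lab in labels):
        row = next(i for i, lab in enumerate(labels) if lab in ("", "nan"))
        raise SchemaError(f"{path.name}: missing label at data row {row + 1}")
    ids = (body["sample_id"].to_numpy(dtype=str)
           if "sample_id" in header else None)
    axis_cols = [c for c in header if c not in ("label", "sample_id")]
    try:
        axis = np.array([float(c) for c in axis_cols])
    except ValueError as exc:
        raise ParseError(f"{path.name}: non-numeric axis value ({exc})") from None
    raw = body[axis_cols].to_numpy(dtype=object)
    numeric = np.empty(raw.shape)
    for (r, c), cell in np.ndenumerate(raw):
        try:
            numeric[r, c] = float(cell)  # exact round-trip parse
            ok = not np.isnan(numeric[r, c])
        except (TypeError, ValueError):
            ok = False
        if not ok:
            # +2: header line plus 1-based counting
            raise ParseError(
                f"{path.name}: line {r + 2} is malformed — missing or "
                f"non-numeric absorbance in channel column {axis_cols[c]!r}"
            )
    return SpectralDataset(absorbance=numeric, axis=axis, labels=labels,
                           sample_ids=ids)


def read_long(path) -> SpectralDataset:
    """Read long-format spectra: columns sample_id, wavelength, absorbance, label."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    needed = {"sample_id", "wavelength", "absorbance", "label"}
    if not needed.issubset(df.columns):
        raise SchemaError(
            f"{path.name}: long format needs columns {sorted(needed)}"
        )
    wide = df.pivot_table(index="sample_id", columns="wavelength",
                          values="absorbance", sort=False)
    wide = wide[sorted(wide.columns)]
    lab = df.drop_duplicates("sample_id").set_index("sample_id")["label"]
    if wide.isna().any().any():
        raise ParseError(f"{path.name}: incomplete sample/wavelength grid")
    return SpectralDataset(
        absorbance=wide.to_numpy(dtype=float),
        axis=wide.columns.to_numpy(dtype=float),
        labels=lab.loc[wide.index].to_numpy(dtype=str),
        sample_ids=wide.index.to_numpy(dtype=str),
    )


def write_matrix(ds: SpectralDataset, path) -> Path:
    """Write a dataset so that :func:`read_matrix` round-trips it.

    Column order is deterministic: sample_id, label, then the axis values in
    stored order.  Floats are written with shortest round-trip repr, so the
    absorbance survives a write/read cycle bit-for-bit.
    """
    path = Path(path)
    cells = [[repr(float(v)) for v in row] for row in ds.absorbance]
    df = pd.DataFrame(cells, columns=[repr(float(v)) for v in ds.axis])
    df.insert(0, "label", ds.labels)
    df.insert(0, "sample_id", ds.sample_ids)
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


def stratified_split(ds: SpectralDataset, ratio: tuple[int, int] = (2, 1),
                     seed: int = 0) -> SplitResult:
    """Per-class random train/test partition at the requested ratio.

    For a class of size n and ratio a:b the train count is
    ``floor(n*a/(a+b))`` with the remainder going to the test set, so the
    test set is never short-changed by rounding.  Assignment is a
    deterministic function of ``seed``.
    """
    a, b = int(ratio[0]), int(ratio[1])
    if a < 1 or b < 1:
        raise ConfigError(f"ratio parts must be positive, got {a}:{b}")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in ds.classes:
        idx = np.flatnonzero(ds.labels == c)
        if idx.size < a + b:
            raise ConfigError(
                f"class {c!r} has {idx.size} samples, fewer than the "
                f"ratio sum {a + b}"
            )
        perm = rng.permutation(idx)
        n_train = (idx.size * a) // (a + b)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return SplitResult(train=ds.select(tr), test=ds.select(te),
                       ratio=(a, b), seed=int(seed))


def class_mean_spectra(ds: SpectralDataset) -> np.ndarray:
    """Per-class mean spectra, rows ordered by sorted label."""
    if ds.n_samples == 0:
        raise SchemaError("empty dataset")
    return np.vstack([
        ds.absorbance[ds.labels == c].mean(axis=0) for c in ds.classes
    ])
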