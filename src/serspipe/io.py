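"""Core spectra containers and delimited-matrix readers/writers.

A spectra matrix is T acquisitions (rows) by W frequency channels (columns) of
non-negative detector intensities.  On disk it is a delimited text matrix whose
optional first row holds the wavenumber axis (cm^-1, strictly increasing); each
subsequent row is one spectrum.  Background-corrected spectra share the layout
but are signed.

Internally all indexing is 0-based with half-open intervals; user-facing tables
and reports use 1-based closed intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

_DELIMS = {"csv": ",", "tsv": "\t"}


def _delimiter(dialect: str) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise ValidationError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'") from None


@dataclass
class SpectraMatrix:
    """Raw spectra: ``intensities[t, j]`` is the intensity of frequency channel
    ``j`` at acquisition ``t``.

    Parameters
    ----------
    intensities
        (T, W) array of finite, non-negative reals (arbitrary detector units).
    wavenumber
        Optional length-W strictly increasing axis (cm^-1).  When absent the
        1-based channel index is used as the axis.
    time_index
        Length-T 1-based acquisition indices; defaults to ``1..T``.
    """

    intensities: np.ndarray
    wavenumber: Optional[np.ndarray] = None
    time_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 1:
            raise ValidationError(f"intensities must be a 2-D matrix, got shape {x.shape}")
        if not np.isfinite(x).all():
            t, j = np.argwhere(~np.isfinite(x))[0]
            raise ValidationError(f"non-finite intensity at row {t + 1}, column {j + 1}")
        if (x < 0).any():
            t, j = np.argwhere(x < 0)[0]
            raise ValidationError(
                f"negative intensity {x[t, j]!r} at row {t + 1}, column {j + 1}; "
                "raw spectra must be non-negative"
            )
        self.intensities = x
        self.wavenumber = _check_wavenumber(self.wavenumber, x.shape[1])
        if self.time_index is None:
            self.time_index = np.arange(1, x.shape[0] + 1)
        else:
            self.time_index = np.asarray(self.time_index, dtype=int)
            if self.time_index.shape != (x.shape[0],):
                raise ValidationError("time_index length must equal the number of spectra")

    @property
    def T(self) -> int:
        return self.intensities.shape[0]

    @property
    def W(self) -> int:
        return self.intensities.shape[1]

    @property
    def axis(self) -> np.ndarray:
        """Wavenumber axis, or the 1-based channel index when none was given."""
        if self.wavenumber is not None:
            return self.wavenumber
        return np.arange(1, self.W + 1, dtype=float)


@dataclass
class CorrectedSpectra:
    """Background-removed spectra (signed), same layout as the source matrix.

    ``provenance`` records the window sizes and percentile used for removal.
    """

    values: np.ndarray
    wavenumber: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.values, dtype=float)
        if y.ndim != 2 or y.shape[0] < 1 or y.shape[1] < 1:
            raise ValidationError(f"values must be a 2-D matrix, got shape {y.shape}")
        if not np.isfinite(y).all():
            t, j = np.argwhere(~np.isfinite(y))[0]
            raise ValidationError(f"non-finite corrected value at row {t + 1}, column {j + 1}")
        self.values = y
        self.wavenumber = _check_wavenumber(self.wavenumber, y.shape[1])

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def W(self) -> int:
        return self.values.shape[1]


def _check_wavenumber(w, width: int):
    if w is None:
        return None
    w = np.asarray(w, dtype=float)
    if w.shape != (width,):
        raise ValidationError(f"wavenumber length {w.shape} does not match {width} channels")
    if not np.isfinite(w).all():
        raise ValidationError("wavenumber axis contains non-finite values")
    if np.any(np.diff(w) <= 0):
        j = int(np.argwhere(np.diff(w) <= 0)[0][0])
        raise ValidationError(
            f"wavenumber axis is not strictly increasing between columns {j + 1} and {j + 2}"
        )
    return w


def _read_matrix(path, dialect: str, has_header: bool):
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sep = _delimiter(dialect)
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str, engine="c", comment=None)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed delimited matrix: {exc}") from exc
    if df.shape[0] < (2 if has_header else 1):
        raise ParseError(f"{path}: no data rows")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    try:
        values[:] = raw
    except ValueError:
        for (r, c), cell in np.ndenumerate(raw):
            try:
                float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: malformed numeric cell {cell!r} at row {r + 1}, column {c + 1}"
                ) from None
        raise ParseError(f"{path}: malformed numeric content") from None
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: missing/short cell at row {r + 1}, column {c + 1} (ragged row?)"
        )
    if has_header:
        return values[0], values[1:]
    return None, values


def read_spectra(path, dialect: str = "tsv", has_header: bool = True) -> SpectraMatrix:
    """Read a raw spectra matrix from a delimited text file.

    The first row is the wavenumber header unless ``has_header=False``, in which
    case every row is a spectrum and the channel index serves as the axis.
    Negative or non-finite intensities are rejected.
    """
    header, values = _read_matrix(path, dialect, has_header)
    return SpectraMatrix(intensities=values, wavenumber=header)


def read_corrected(path, dialect: str = "tsv", has_header: bool = True) -> CorrectedSpectra:
    """Read a background-corrected matrix (signed values allowed)."""
    header, values = _read_matrix(path, dialect, has_header)
    return CorrectedSpectra(values=values, wavenumber=header)


def write_spectra(m, path, dialect: str = "tsv") -> Path:
    """Write a :class:`SpectraMatrix` or :class:`CorrectedSpectra` to disk.

    Values are written with 17 significant digits so the read/write round trip
    is bit-faithful for float64.  Returns the path written.
    """
    path = Path(path)
    sep = _delimiter(dialect)
    if isinstance(m, SpectraMatrix):
        values = m.intensities
    elif isinstance(m, CorrectedSpectra):
        values = m.values
    else:
        raise ValidationError(f"cannot write object of type {type(m).__name__}")
    axis = m.wavenumber if m.wavenumber is not None else np.arange(1, values.shape[1] + 1)
    with open(path, "w") as fh:
        fh.write(sep.join(_fmt(v) for v in axis) + "\n")
        for row in values:
            fh.write(sep.join(_fmt(v) for v in row) + "\n")
    return path


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


def replace(obj, **changes):
    """Dataclass ``replace`` re-exported for convenience on the container types."""
    return dataclasses.replace(obj, **changes)
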