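"""Wavelength grids, spectral curve containers, resampling and CSV I/O.

Everything downstream (filter models, the imaging chain, reconstruction)
operates on curves sampled on a shared :class:`WavelengthGrid`.  Spectral
integrals use the rectangle rule with weight ``step`` throughout the
package, so that the diagonal-matrix forward model and the band-energy
integral share one quadrature convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    GridError,
    ParameterError,
    SpectraFormatError,
    SpectralRangeError,
)

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "ReflectanceDataset",
    "Illuminant",
    "DEFAULT_GRID",
    "resample",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_curves_csv",
    "write_curves_csv",
]

#: Spectrum kinds bounded above by 1 (plus tolerance).
_BOUNDED_KINDS = frozenset({"reflectance", "transmission"})
_KINDS = frozenset({"reflectance", "transmission", "spd", "qe"})

WAVELENGTH_COLUMN = "wavelength_nm"


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, inclusive wavelength grid in nanometres."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise GridError(f"start must be < stop (got {self.start}, {self.stop})")
        if not self.step > 0:
            raise GridError(f"step must be > 0 (got {self.step})")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-6:
            raise GridError(
                f"(stop - start) = {self.stop - self.start} is not divisible "
                f"by step = {self.step}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    def covers(self, other: "WavelengthGrid") -> bool:
        return self.start <= other.start + 1e-9 and other.stop <= self.stop + 1e-9

    @classmethod
    def from_wavelengths(cls, wavelengths: np.ndarray) -> "WavelengthGrid":
        """Build a grid from an explicit uniformly spaced wavelength vector."""
        w = np.asarray(wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise GridError("need a 1-D vector of at least two wavelengths")
        steps = np.diff(w)
        if np.any(steps <= 0):
            raise SpectraFormatError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise GridError("wavelengths are not uniformly spaced")
        return cls(float(w[0]), float(w[-1]), float(steps[0]))


#: Default modeling grid: 380-1000 nm at 1 nm.
DEFAULT_GRID = WavelengthGrid(380.0, 1000.0, 1.0)


@dataclass
class Spectrum:
    """A sampled spectral curve of a declared kind.

    ``reflectance`` and ``transmission`` curves are unitless in [0, 1];
    ``spd`` (illuminant power) and ``qe`` (sensor quantum efficiency) are
    non-negative in arbitrary linear units.  NaN entries are permitted and
    mean "masked / not measured" (used by sweep characterization).
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "reflectance"
    #: headroom above 1 tolerated for bounded kinds (measurement noise).
    tol: float = 1e-6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _KINDS:
            raise ParameterError(
                f"unknown spectrum kind {self.kind!r}; expected one of {sorted(_KINDS)}"
            )
        if self.values.ndim != 1 or self.values.size != self.grid.n_points:
            raise GridError(
                f"values length {self.values.size} != grid points {self.grid.n_points}"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < -1e-12:
            raise ParameterError(
                f"{self.kind} spectrum has negative value ({finite.min()})"
            )
        if self.kind in _BOUNDED_KINDS and finite.size and finite.max() > 1 + self.tol:
            raise ParameterError(
                f"{self.kind} spectrum exceeds 1 ({finite.max()} > 1 + {self.tol})"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths()

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ReflectanceDataset:
    """K reflectance samples on a common grid, with a species label each."""

    grid: WavelengthGrid
    samples: np.ndarray
    labels: Sequence[str]
    #: "strict" enforces per-row reflectance bounds; "none" skips them
    #: (reconstructed spectra may dip below 0 / above 1 before clipping).
    validate: str = "strict"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.labels = list(self.labels)
        if self.samples.shape[0] < 1:
            raise GridError("dataset needs at least one sample")
        if self.samples.shape[1] != self.grid.n_points:
            raise GridError(
                f"sample length {self.samples.shape[1]} != grid points {self.grid.n_points}"
            )
        if len(self.labels) != self.samples.shape[0]:
            raise GridError("one label per sample required")
        if self.validate == "strict":
            for row in self.samples:
                Spectrum(self.grid, row, kind="reflectance", tol=1e-6)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.samples.shape[1]

    def spectrum(self, k: int) -> Spectrum:
        return Spectrum(self.grid, self.samples[k], kind="reflectance", tol=np.inf)


@dataclass
class Illuminant:
    """A named spectral power distribution."""

    name: str
    spd: Spectrum

    def __post_init__(self) -> None:
        if self.spd.kind != "spd":
            raise GridError("illuminant curve must have kind 'spd'")
        if not np.any(self.spd.values > 0):
            raise DegenerateInputError(f"illuminant {self.name!r} is identically zero")


def resample(s: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``; no extrapolation."""
    src = s.grid
    if target.start < src.start - 1e-9 or target.stop > src.stop + 1e-9:
        raise SpectralRangeError(
            f"target range [{target.start}, {target.stop}] exceeds source "
            f"range [{src.start}, {src.stop}]"
        )
    values = np.interp(target.wavelengths(), src.wavelengths(), s.values)
    return Spectrum(target, values, kind=s.kind, tol=s.tol)


# ---------------------------------------------------------------------------
# CSV dialect: UTF-8, comma separated, first column "wavelength_nm",
# one column per sample/curve, header row carries labels.
# ---------------------------------------------------------------------------


def _read_table(path) -> tuple[WavelengthGrid, np.ndarray, list[str]]:
    # header parsed by hand: sample labels may repeat (species names) and
    # pandas would otherwise mangle duplicates
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(header) < 2:
        raise SpectraFormatError(f"{path}: need a wavelength column plus >= 1 curve")
    if header[0] != WAVELENGTH_COLUMN:
        raise SpectraFormatError(
            f"{path}: first column must be {WAVELENGTH_COLUMN!r}, got {header[0]!r}"
        )
    df = pd.read_csv(path, skiprows=1, header=None)
    if df.shape[1] != len(header):
        raise SpectraFormatError(f"{path}: ragged columns")
    if df.isna().any().any():
        raise SpectraFormatError(f"{path}: ragged or missing entries")
    w = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(w) <= 0):
        raise SpectraFormatError(f"{path}: wavelengths must be strictly increasing")
    grid = WavelengthGrid.from_wavelengths(w)
    values = df.iloc[:, 1:].to_numpy(dtype=float).T  # one row per curve
    return grid, values, header[1:]


def _write_table(path, grid: WavelengthGrid, values: np.ndarray, names: Iterable[str]) -> None:
    values = np.atleast_2d(values)
    df = pd.DataFrame(
        np.column_stack([grid.wavelengths(), values.T]),
        columns=[WAVELENGTH_COLUMN, *names],
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def read_spectra_csv(path) -> ReflectanceDataset:
    """Read a reflectance dataset from the spectra CSV dialect."""
    grid, values, labels = _read_table(path)
    return ReflectanceDataset(grid, values, labels)


def write_spectra_csv(ds: ReflectanceDataset, path) -> None:
    _write_table(path, ds.grid, ds.samples, ds.labels)


def read_curves_csv(path) -> tuple[WavelengthGrid, np.ndarray, list[str]]:
    """Read arbitrary named curves (QE, SPD, transmissions) from CSV."""
    return _read_table(path)


def write_curves_csv(path, grid: WavelengthGrid, values: np.ndarray, names: Iterable[str]) -> None:
    _write_table(path, grid, values, names)
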