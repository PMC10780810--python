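"""Gaussian interference-filter model and the measured VIS/NIR filter banks.

An interference filter is idealized as a peak-normalized Gaussian
``u(lambda) = alpha * exp(-(lambda - mu)^2 / (2 sigma^2))`` with
``sigma = fwhm / (2 sqrt(2 ln 2))``; ``alpha`` is the peak transmission
(Tmax).  The two fabricated eight-band banks are shipped as Gaussian
approximations built from their measured (centering, FWHM, Tmax) triples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GridError, ParameterError
from .spectral import (
    DEFAULT_GRID,
    Spectrum,
    WavelengthGrid,
    read_curves_csv,
    write_curves_csv,
)

__all__ = [
    "GaussianFilterSpec",
    "FilterBank",
    "sigma_from_fwhm",
    "gaussian_transmission",
    "measured_bank",
    "measured_bank_table",
    "VIS_BANK_TABLE",
    "NIR_BANK_TABLE",
]

#: 2 * sqrt(2 * ln 2): FWHM of a unit-sigma Gaussian.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def sigma_from_fwhm(fwhm: float) -> float:
    """Gaussian standard deviation for a given full width at half maximum."""
    if fwhm <= 0:
        raise ParameterError(f"fwhm must be > 0, got {fwhm}")
    return fwhm / FWHM_PER_SIGMA


@dataclass(frozen=True)
class GaussianFilterSpec:
    """Center, width and peak transmission of one Gaussian bandpass filter."""

    center: float
    fwhm: float
    peak: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ParameterError(f"fwhm must be > 0, got {self.fwhm}")
        if not 0 < self.peak <= 1:
            raise ParameterError(f"peak must be in (0, 1], got {self.peak}")

    @property
    def sigma(self) -> float:
        return sigma_from_fwhm(self.fwhm)


def gaussian_transmission(spec: GaussianFilterSpec, grid: WavelengthGrid) -> Spectrum:
    """Evaluate the Gaussian transmission curve of ``spec`` on ``grid``."""
    lam = grid.wavelengths()
    u = spec.peak * np.exp(-((lam - spec.center) ** 2) / (2.0 * spec.sigma**2))
    return Spectrum(grid, u, kind="transmission")


@dataclass
class FilterBank:
    """An ordered set of transmission curves sharing one grid."""

    grid: WavelengthGrid
    bands: list[Spectrum]
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.bands) < 1:
            raise GridError("filter bank needs at least one band")
        if len(self.names) != len(self.bands):
            raise GridError("one name per band required")
        for b in self.bands:
            if b.grid != self.grid:
                raise GridError("all bands must share the bank grid")
            if b.kind != "transmission":
                raise GridError("bank curves must have kind 'transmission'")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def transmission_matrix(self) -> np.ndarray:
        """n_bands x n_wavelengths matrix of transmissions."""
        return np.vstack([b.values for b in self.bands])

    @classmethod
    def from_specs(
        cls,
        specs: Sequence[GaussianFilterSpec],
        grid: WavelengthGrid = DEFAULT_GRID,
        names: Sequence[str] | None = None,
    ) -> "FilterBank":
        if names is None:
            names = [f"P{i + 1}" for i in range(len(specs))]
        bands = [gaussian_transmission(s, grid) for s in specs]
        return cls(grid, bands, list(names))

    def to_csv(self, path) -> None:
        write_curves_csv(path, self.grid, self.transmission_matrix(), self.names)

    @classmethod
    def from_csv(cls, path) -> "FilterBank":
        grid, values, names = read_curves_csv(path)
        bands = [Spectrum(grid, row, kind="transmission", tol=0.05) for row in values]
        return cls(grid, bands, names)


# Measured characteristics of the two fabricated eight-band MSFAs:
# (band, specified centering nm, measured centering nm, FWHM nm, Tmax %).
VIS_BANK_TABLE: tuple[tuple[str, float, float, float, float], ...] = (
    ("P1", 421, 425, 71, 41),
    ("P2", 457, 460, 52, 48),
    ("P3", 493, 500, 44, 53),
    ("P4", 529, 510, 39, 57),
    ("P5", 565, 560, 36, 62),
    ("P6", 601, 590, 34, 62),
    ("P7", 637, 630, 33, 63),
    ("P8", 673, 660, 33, 63),
)

NIR_BANK_TABLE: tuple[tuple[str, float, float, float, float], ...] = (
    ("P1", 688, 670, 31, 55),
    ("P2", 718, 705, 30, 53),
    ("P3", 748, 735, 30, 53),
    ("P4", 778, 760, 29, 52),
    ("P5", 808, 810, 30, 51),
    ("P6", 838, 840, 28, 49),
    ("P7", 868, 860, 27, 49),
    ("P8", 898, 885, 27, 47),
)


def measured_bank_table(which: str) -> tuple[tuple[str, float, float, float, float], ...]:
    """Raw (band, specified center, measured center, fwhm, tmax%) rows."""
    key = which.upper()
    if key == "VIS":
        return VIS_BANK_TABLE
    if key == "NIR":
        return NIR_BANK_TABLE
    raise ParameterError(f"which must be 'VIS' or 'NIR', got {which!r}")


def measured_bank(which: str, grid: WavelengthGrid = DEFAULT_GRID) -> FilterBank:
    """Gaussian model of a fabricated bank from its measured characteristics."""
    rows = measured_bank_table(which)
    specs = [
        GaussianFilterSpec(center=meas, fwhm=fwhm, peak=tmax / 100.0)
        for (_, _spec_center, meas, fwhm, tmax) in rows
    ]
    return FilterBank.from_specs(specs, grid=grid, names=[r[0] for r in rows])
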