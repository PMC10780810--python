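"""Simulated monochromator-sweep characterization of a hybrid sensor.

A monochromatic line is stepped across the support (default 5 nm steps);
the bare sensor's response and the per-band responses of the hybrid sensor
are recorded, and each filter's transmission is recovered as the ratio
band/bare wherever the bare response is above a floor.  A report extracts
(centering, FWHM, Tmax) per band via half-maximum crossings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, SpectralRangeError
from .filters import FilterBank
from .spectral import Spectrum, WavelengthGrid, resample

__all__ = [
    "SweepStack",
    "simulate_sweep",
    "estimate_filter_response",
    "characterization_report",
]


@dataclass
class SweepStack:
    """Responses recorded at each sweep wavelength."""

    wavelengths: np.ndarray
    bare_response: np.ndarray
    band_responses: np.ndarray
    band_names: list[str]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.bare_response = np.asarray(self.bare_response, dtype=float)
        self.band_responses = np.atleast_2d(np.asarray(self.band_responses, dtype=float))
        n = self.wavelengths.size
        if self.bare_response.size != n or self.band_responses.shape[1] != n:
            raise ParameterError("sweep vectors must share one length")
        if np.any(self.bare_response < 0) or np.any(self.band_responses < 0):
            raise ParameterError("sweep responses must be >= 0")


def simulate_sweep(
    qe: Spectrum,
    bank: FilterBank,
    start: float | None = None,
    stop: float | None = None,
    step: float = 5.0,
    noise_snr: float = np.inf,
    seed: int | None = None,
) -> SweepStack:
    """Sweep a monochromatic line over [start, stop] in ``step`` nm steps.

    At each line wavelength the bare response is ``qe`` and band ``i``'s
    response is ``qe * u_i`` (constant integration time modeled as unit
    gain).  Optional additive Gaussian noise with std
    ``mean(bare) / noise_snr``, clipped at zero.
    """
    if step <= 0:
        raise ParameterError(f"step must be > 0, got {step}")
    src = qe.grid
    if start is None:
        start = src.start
    if stop is None:
        stop = src.stop
    if start < src.start - 1e-9 or stop > src.stop + 1e-9 or start >= stop:
        raise SpectralRangeError(
            f"sweep [{start}, {stop}] outside curve support [{src.start}, {src.stop}]"
        )
    n_steps = int(np.floor((stop - start) / step + 1e-9))
    sweep_grid = WavelengthGrid(start, start + n_steps * step, step)
    bare = resample(qe, sweep_grid).values.copy()
    bands = np.vstack(
        [bare * resample(b, sweep_grid).values for b in bank.bands]
    )
    if np.isfinite(noise_snr):
        if noise_snr <= 0:
            raise ParameterError(f"noise_snr must be > 0, got {noise_snr}")
        rng = np.random.default_rng(seed)
        std = float(np.mean(np.abs(bare)) / noise_snr)
        bare = np.maximum(bare + rng.normal(0, std, bare.shape), 0.0)
        bands = np.maximum(bands + rng.normal(0, std, bands.shape), 0.0)
    return SweepStack(sweep_grid.wavelengths(), bare, bands, list(bank.names))


def estimate_filter_response(stack: SweepStack, floor: float = 0.05) -> FilterBank:
    """Recover transmissions as band/bare where the bare signal is usable.

    Wavelengths where ``bare < floor * max(bare)`` are masked (NaN).
    Estimates are clipped to [0, 1.05] to absorb noise overshoot.
    """
    if not 0 < floor < 1:
        raise ParameterError(f"floor must be in (0, 1), got {floor}")
    bare = stack.bare_response
    if bare.max() <= 0:
        raise DegenerateInputError("bare response is zero everywhere")
    threshold = floor * bare.max()
    usable = bare >= threshold
    if not usable.any():
        raise DegenerateInputError("bare response is below the floor everywhere")
    grid = WavelengthGrid.from_wavelengths(stack.wavelengths)
    bands = []
    for row in stack.band_responses:
        t = np.full(row.shape, np.nan)
        t[usable] = np.clip(row[usable] / bare[usable], 0.0, 1.05)
        bands.append(Spectrum(grid, t, kind="transmission", tol=0.05))
    return FilterBank(grid, bands, list(stack.band_names))


def _half_max_width(lam: np.ndarray, t: np.ndarray, peak_idx: int) -> float:
    """FWHM by linear-interpolated half-maximum crossings around the peak."""
    half = t[peak_idx] / 2.0

    def crossing(direction: int) -> float:
        i = peak_idx
        while 0 <= i + direction < t.size and not np.isnan(t[i + direction]):
            j = i + direction
            if t[j] < half:
                # linear interpolation between i and j
                frac = (t[i] - half) / (t[i] - t[j])
                return lam[i] + frac * (lam[j] - lam[i])
            i = j
        return lam[i]  # ran off the usable support

    return abs(crossing(+1) - crossing(-1))


def characterization_report(est: FilterBank) -> pd.DataFrame:
    """Per-band (centering, FWHM, Tmax) from estimated transmissions."""
    lam = est.grid.wavelengths()
    rows = []
    for name, band in zip(est.names, est.bands):
        t = band.values
        if not np.any(np.isfinite(t)):
            raise DegenerateInputError(f"band {name} is fully masked")
        tmax = np.nanmax(t)
        peaks = np.where(t == tmax)[0]
        if peaks.size > 1:
            warnings.warn(
                f"band {name}: plateau maximum, tie broken toward lower wavelength",
                stacklevel=2,
            )
        peak_idx = int(peaks[0])
        rows.append(
            {
                "Band": name,
                "Centering (nm)": float(lam[peak_idx]),
                "FWHM (nm)": _half_max_width(lam, t, peak_idx),
                "Tmax": float(tmax),
            }
        )
    return pd.DataFrame(rows)
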