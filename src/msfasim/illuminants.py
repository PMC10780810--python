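"""Standard-ish illuminants tabulated on arbitrary grids.

Illuminant A is Planck's law at 2856 K (its defining temperature) and
"tungsten" is Planck at 3200 K, both normalized to 100 at 560 nm.
Illuminant E is flat.  The daylight simulator ("D65") is approximated by a
6504 K blackbody with the same normalization: the tabulated standard is
undefined past 830 nm, while the NIR camera needs support to 1000 nm, and
the simulator lamp used in practice is itself only an approximation.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .spectral import Illuminant, Spectrum, WavelengthGrid, DEFAULT_GRID

__all__ = ["planck_spd", "get_illuminant", "ILLUMINANT_NAMES"]

# Planck radiation constants (CODATA), nm-based second constant.
_C2_NM_K = 1.4388e7  # nm * K


def planck_spd(temperature_k: float, grid: WavelengthGrid) -> Spectrum:
    """Blackbody spectral power distribution, normalized to 100 at 560 nm."""
    if temperature_k <= 0:
        raise ParameterError(f"temperature must be > 0, got {temperature_k}")
    lam = grid.wavelengths()

    def radiance(lmbd: np.ndarray) -> np.ndarray:
        return lmbd**-5.0 / np.expm1(_C2_NM_K / (lmbd * temperature_k))

    values = 100.0 * radiance(lam) / radiance(np.array([560.0]))[0]
    return Spectrum(grid, values, kind="spd")


ILLUMINANT_NAMES = ("A", "D65", "E", "tungsten")


def get_illuminant(name: str, grid: WavelengthGrid = DEFAULT_GRID) -> Illuminant:
    """Return a named illuminant tabulated on ``grid``."""
    key = name.strip().lower()
    if key == "a":
        return Illuminant("A", planck_spd(2856.0, grid))
    if key == "d65":
        return Illuminant("D65", planck_spd(6504.0, grid))
    if key == "e":
        values = np.full(grid.n_points, 100.0)
        return Illuminant("E", Spectrum(grid, values, kind="spd"))
    if key == "tungsten":
        return Illuminant("tungsten", planck_spd(3200.0, grid))
    raise ParameterError(
        f"unknown illuminant {name!r}; available: {', '.join(ILLUMINANT_NAMES)}"
    )
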