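"""Forward model of the camera: band responses, noise, and energy balance.

The system matrix folds sensor sensitivity, per-band filter transmission,
illuminant power and the rectangle-rule quadrature weight into one
``n_bands x n_wavelengths`` operator, so a sample's band responses are a
single matrix-vector product.  Noise is additive white Gaussian with
standard deviation ``mean(|response|) / snr``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, GridError, ParameterError
from .filters import FilterBank
from .spectral import Illuminant, ReflectanceDataset, Spectrum

__all__ = [
    "CameraResponseSet",
    "EnergyBalanceReport",
    "system_matrix",
    "camera_response",
    "noise_std_for_snr",
    "energy_balance",
]


@dataclass
class CameraResponseSet:
    """Band responses for every dataset sample (n_bands x K, linear units)."""

    responses: np.ndarray
    snr: float = np.inf
    seed: int | None = None

    def __post_init__(self) -> None:
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if not np.all(np.isfinite(self.responses)):
            raise ParameterError("responses must be finite")

    @property
    def n_bands(self) -> int:
        return self.responses.shape[0]

    @property
    def n_samples(self) -> int:
        return self.responses.shape[1]


def system_matrix(qe: Spectrum, bank: FilterBank, illum: Illuminant) -> np.ndarray:
    """Rows ``qe * u_i * spd * step`` of the linear imaging operator."""
    if qe.grid != bank.grid or illum.spd.grid != bank.grid:
        raise GridError("qe, bank and illuminant must share one grid")
    weights = qe.values * illum.spd.values * bank.grid.step
    return bank.transmission_matrix() * weights[np.newaxis, :]


def noise_std_for_snr(noiseless: np.ndarray, snr: float) -> float:
    """Std of the additive Gaussian noise implied by a target SNR."""
    if snr <= 0:
        raise ParameterError(f"snr must be > 0, got {snr}")
    if np.isinf(snr):
        return 0.0
    return float(np.mean(np.abs(noiseless)) / snr)


def camera_response(
    A: np.ndarray,
    ds: ReflectanceDataset,
    snr: float = np.inf,
    seed: int | None = None,
) -> CameraResponseSet:
    """Simulate band responses ``A r_k`` for every sample, with optional noise."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[1] != ds.n_wavelengths:
        raise GridError(
            f"system matrix has {A.shape[1]} columns but dataset has "
            f"{ds.n_wavelengths} grid points"
        )
    noiseless = A @ ds.samples.T
    std = noise_std_for_snr(noiseless, snr)
    if std > 0:
        rng = np.random.default_rng(seed)
        responses = noiseless + rng.normal(0.0, std, size=noiseless.shape)
    else:
        responses = noiseless
    return CameraResponseSet(responses, snr=snr, seed=seed)


@dataclass
class EnergyBalanceReport:
    """Per-band integrated responses under one illuminant, plus the
    multiplicative factors that equalize them."""

    rho: np.ndarray
    illuminant_name: str
    balance_factors: np.ndarray
    band_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"band": self.band_names, "rho": self.rho, "factor": self.balance_factors}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def energy_balance(
    illum: Illuminant,
    band_responses: list[Spectrum],
    names: list[str] | None = None,
) -> EnergyBalanceReport:
    """Integrate each band's response curve against the illuminant.

    ``rho_p = sum_lambda I(lambda) * S_p(lambda) * step``; factors are
    ``max(rho) / rho_p`` so that after balancing all bands respond equally
    to the perfect diffuser.
    """
    if not band_responses:
        raise DegenerateInputError("need at least one band response")
    grid = illum.spd.grid
    for s in band_responses:
        if s.grid != grid:
            raise GridError("band responses must share the illuminant grid")
    S = np.vstack([s.values for s in band_responses])
    rho = S @ illum.spd.values * grid.step
    if np.any(rho <= 0):
        dead = [i for i, r in enumerate(rho) if r <= 0]
        raise DegenerateInputError(f"bands {dead} have zero integrated response")
    factors = rho.max() / rho
    if names is None:
        names = [f"P{i + 1}" for i in range(len(band_responses))]
    return EnergyBalanceReport(rho, illum.name, factors, list(names))
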