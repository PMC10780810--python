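"""Wiener reflectance reconstruction and spectral/colorimetric metrics.

The estimator uses the dataset's second-moment (autocorrelation) matrix,
``C_r = (1/K) sum_k r_k r_k^T``, and the standard linear-MMSE closed form
``W = C_r A^T (A C_r A^T + v I)^(-1)`` with ``v`` the noise variance.  The
solve goes through a Cholesky factorization, never an explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .colorimetry import delta_e2000_spectra
from .errors import DegenerateInputError, RegularizationError, ShapeError
from .imaging import CameraResponseSet
from .spectral import Illuminant, ReflectanceDataset

__all__ = [
    "WienerEstimator",
    "ReconstructionReport",
    "fit_wiener",
    "reconstruct",
    "rms",
    "gfc",
    "delta_e2000",
    "evaluate",
]

#: Row labels of the exported summary table, in export order.
REPORT_ROWS = (
    "Min Delta E 2000",
    "Max Delta E 2000",
    "Mean Delta E 2000",
    "Median E 2000",
    "STD Delta E 2000",
    "Min RMS",
    "Max RMS",
    "Mean RMS",
    "GFC > 0.99",
    "GFC > 0.95",
)


@dataclass
class WienerEstimator:
    """Linear reconstruction operator plus the statistics that built it."""

    W: np.ndarray
    autocorrelation: np.ndarray
    noise_variance: float

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if not np.all(np.isfinite(self.W)):
            raise ShapeError("W must be finite")


def fit_wiener(
    A: np.ndarray, ds: ReflectanceDataset, noise_variance: float = 0.0
) -> WienerEstimator:
    """Fit the Wiener reconstruction matrix for system ``A`` on ``ds``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[1] != ds.n_wavelengths:
        raise ShapeError(
            f"A has {A.shape[1]} columns, dataset has {ds.n_wavelengths} grid points"
        )
    if noise_variance < 0:
        raise ShapeError(f"noise_variance must be >= 0, got {noise_variance}")
    R = ds.samples
    C_r = (R.T @ R) / ds.n_samples
    CA = C_r @ A.T  # n_lambda x n_bands
    M = A @ CA + noise_variance * np.eye(A.shape[0])
    try:
        c, low = cho_factor(M)
    except LinAlgError as exc:
        raise RegularizationError(
            "A C_r A^T + v I is singular; pass noise_variance > 0"
        ) from exc
    # W = CA M^-1; M symmetric, so solve M X = CA^T and transpose.
    W = cho_solve((c, low), CA.T).T
    return WienerEstimator(W=W, autocorrelation=C_r, noise_variance=noise_variance)


def reconstruct(
    est: WienerEstimator,
    O: CameraResponseSet,
    grid,
    labels=None,
    clip: bool = False,
) -> ReflectanceDataset:
    """Apply the estimator to band responses, returning spectra estimates.

    Estimates are not clipped to [0, 1] unless ``clip=True``; the returned
    dataset therefore skips reflectance-bound validation.
    """
    if est.W.shape[1] != O.n_bands:
        raise ShapeError(
            f"W expects {est.W.shape[1]} bands, responses have {O.n_bands}"
        )
    R_hat = (est.W @ O.responses).T  # K x n_lambda
    if clip:
        R_hat = np.clip(R_hat, 0.0, 1.0)
    if labels is None:
        labels = [f"s{k:04d}" for k in range(R_hat.shape[0])]
    return ReflectanceDataset(grid, R_hat, labels, validate="none")


def rms(r: np.ndarray, r_hat: np.ndarray) -> float:
    """Root-mean-square difference between two equal-length vectors."""
    r = np.asarray(r, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    if r.shape != r_hat.shape:
        raise ShapeError(f"shape mismatch: {r.shape} vs {r_hat.shape}")
    return float(np.sqrt(np.mean((r - r_hat) ** 2)))


def gfc(r: np.ndarray, r_hat: np.ndarray) -> float:
    """Goodness-of-fit coefficient |<r, r_hat>| / (|r| |r_hat|)."""
    r = np.asarray(r, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    if r.shape != r_hat.shape:
        raise ShapeError(f"shape mismatch: {r.shape} vs {r_hat.shape}")
    nr = np.linalg.norm(r)
    nh = np.linalg.norm(r_hat)
    if nr == 0 or nh == 0:
        raise DegenerateInputError("gfc is undefined for zero vectors")
    return float(abs(np.dot(r, r_hat)) / (nr * nh))


def delta_e2000(r: np.ndarray, r_hat: np.ndarray, illum: Illuminant) -> float:
    """CIEDE2000 between a reflectance and its estimate under ``illum``."""
    grid = illum.spd.grid
    de, _ = delta_e2000_spectra(r, r_hat, grid, illum)
    return float(de[0])


@dataclass
class ReconstructionReport:
    """Per-sample metrics and their summary statistics."""

    rms: np.ndarray
    gfc: np.ndarray
    delta_e2000: np.ndarray
    partial_cmf_support: bool = False
    summary: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.summary is None:
            self.summary = self._summarize()

    @property
    def gfc_over_99(self) -> float:
        return float(np.mean(self.gfc > 0.99))

    @property
    def gfc_over_95(self) -> float:
        return float(np.mean(self.gfc > 0.95))

    def _summarize(self) -> pd.DataFrame:
        de, rm = self.delta_e2000, self.rms
        values = [
            de.min(), de.max(), de.mean(), float(np.median(de)), de.std(ddof=0),
            rm.min(), rm.max(), rm.mean(),
            self.gfc_over_99, self.gfc_over_95,
        ]
        return pd.DataFrame({"value": values}, index=list(REPORT_ROWS))

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index_label="statistic")


def evaluate(
    ds: ReflectanceDataset, ds_hat: ReflectanceDataset, illum: Illuminant
) -> ReconstructionReport:
    """Per-sample RMS / GFC / CIEDE2000 plus summary statistics."""
    if ds.n_samples != ds_hat.n_samples:
        raise ShapeError(
            f"sample counts differ: {ds.n_samples} vs {ds_hat.n_samples}"
        )
    if ds.grid != ds_hat.grid:
        raise ShapeError("datasets must share one grid")
    rms_v = np.array([rms(r, h) for r, h in zip(ds.samples, ds_hat.samples)])
    gfc_v = np.array([gfc(r, h) for r, h in zip(ds.samples, ds_hat.samples)])
    de_v, partial = delta_e2000_spectra(ds.samples, ds_hat.samples, ds.grid, illum)
    return ReconstructionReport(
        rms=rms_v, gfc=gfc_v, delta_e2000=de_v, partial_cmf_support=partial
    )
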