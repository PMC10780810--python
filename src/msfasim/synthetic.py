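"""Seeded generators for vegetation-like spectra, sensor QE and test scenes.

The reflectance generator is an emulation, not leaf physics: each species
archetype is a low visible baseline with chlorophyll absorption wells near
450 and 670 nm, a green peak near 550 nm, a sigmoidal red edge between
roughly 690 and 740 nm rising to a NIR plateau, plus per-sample parameter
jitter and smooth additive noise.  It exists because the measured
reflectance collection behind the camera design is not publicly deposited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import GeometryError, ParameterError
from .filters import FilterBank
from .spectral import DEFAULT_GRID, ReflectanceDataset, Spectrum, WavelengthGrid

__all__ = [
    "VegetationModelParams",
    "gen_reflectance_set",
    "gen_sensor_qe",
    "gen_scene",
    "SpeciesArchetype",
    "SPECIES_NAMES",
]

SPECIES_NAMES = (
    "tomato",
    "cucumber",
    "bell_pepper",
    "bindweed",
    "nutsedge",
    "plantago",
    "potentilla",
    "sorrel",
)


@dataclass(frozen=True)
class VegetationModelParams:
    """Ranges from which species archetypes and samples are drawn."""

    n_samples: int = 626
    n_species: int = 8
    seed: int = 0
    noise_std: float = 0.01
    baseline_range: tuple[float, float] = (0.03, 0.08)
    green_center_range: tuple[float, float] = (540.0, 560.0)
    green_width_range: tuple[float, float] = (25.0, 40.0)
    green_amp_range: tuple[float, float] = (0.05, 0.14)
    red_edge_center_range: tuple[float, float] = (700.0, 730.0)
    red_edge_scale_range: tuple[float, float] = (10.0, 16.0)
    nir_plateau_range: tuple[float, float] = (0.30, 0.60)
    well_depth_range: tuple[float, float] = (0.005, 0.025)

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_species < 1:
            raise ParameterError("n_samples and n_species must be >= 1")
        if self.noise_std < 0:
            raise ParameterError("noise_std must be >= 0")
        if self.nir_plateau_range[1] + self.green_amp_range[1] + self.baseline_range[1] > 1.0:
            raise ParameterError("parameter ranges allow reflectance > 1 pre-clip")


@dataclass(frozen=True)
class SpeciesArchetype:
    """Drawn parameters defining one species' mean spectrum."""

    baseline: float
    green_center: float
    green_width: float
    green_amp: float
    red_edge_center: float
    red_edge_scale: float
    nir_plateau: float
    well_depth: float


def _draw(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    return float(rng.uniform(*lo_hi))


def _archetype(rng: np.random.Generator, p: VegetationModelParams) -> SpeciesArchetype:
    return SpeciesArchetype(
        baseline=_draw(rng, p.baseline_range),
        green_center=_draw(rng, p.green_center_range),
        green_width=_draw(rng, p.green_width_range),
        green_amp=_draw(rng, p.green_amp_range),
        red_edge_center=_draw(rng, p.red_edge_center_range),
        red_edge_scale=_draw(rng, p.red_edge_scale_range),
        nir_plateau=_draw(rng, p.nir_plateau_range),
        well_depth=_draw(rng, p.well_depth_range),
    )


def _render(arch: SpeciesArchetype, lam: np.ndarray) -> np.ndarray:
    base = arch.baseline * np.ones_like(lam)
    # chlorophyll absorption wells near 450 and 670 nm
    base -= arch.well_depth * np.exp(-0.5 * ((lam - 450.0) / 25.0) ** 2)
    base -= arch.well_depth * np.exp(-0.5 * ((lam - 670.0) / 20.0) ** 2)
    green = arch.green_amp * np.exp(
        -0.5 * ((lam - arch.green_center) / arch.green_width) ** 2
    )
    edge = (arch.nir_plateau - arch.baseline) / (
        1.0 + np.exp(-(lam - arch.red_edge_center) / arch.red_edge_scale)
    )
    # mild water-absorption dip near 970 nm
    dip = 0.03 * arch.nir_plateau * np.exp(-0.5 * ((lam - 970.0) / 22.0) ** 2)
    return base + green + edge - dip


def gen_reflectance_set(
    params: VegetationModelParams = VegetationModelParams(),
    grid: WavelengthGrid = DEFAULT_GRID,
) -> ReflectanceDataset:
    """Generate a seeded vegetation-like reflectance dataset on ``grid``."""
    rng = np.random.default_rng(params.seed)
    lam = grid.wavelengths()
    archetypes = [_archetype(rng, params) for _ in range(params.n_species)]
    # spread samples over species as evenly as possible
    counts = np.full(params.n_species, params.n_samples // params.n_species)
    counts[: params.n_samples % params.n_species] += 1

    samples, labels = [], []
    for s, (arch, count) in enumerate(zip(archetypes, counts)):
        name = SPECIES_NAMES[s % len(SPECIES_NAMES)]
        for _ in range(count):
            jittered = SpeciesArchetype(
                baseline=arch.baseline * rng.uniform(0.85, 1.15),
                green_center=arch.green_center + rng.normal(0, 2.0),
                green_width=arch.green_width * rng.uniform(0.9, 1.1),
                green_amp=arch.green_amp * rng.uniform(0.85, 1.15),
                red_edge_center=arch.red_edge_center + rng.normal(0, 2.0),
                red_edge_scale=arch.red_edge_scale * rng.uniform(0.9, 1.1),
                nir_plateau=arch.nir_plateau * rng.uniform(0.9, 1.1),
                well_depth=arch.well_depth * rng.uniform(0.8, 1.2),
            )
            r = _render(jittered, lam)
            if params.noise_std > 0:
                rough = rng.normal(0.0, 1.0, size=lam.size)
                smooth = gaussian_filter1d(rough, sigma=15.0 / grid.step, mode="nearest")
                sd = smooth.std()
                if sd > 0:
                    r = r + params.noise_std * smooth / sd
            samples.append(np.clip(r, 0.0, 1.0))
            labels.append(name)
    return ReflectanceDataset(grid, np.vstack(samples), labels)


def gen_sensor_qe(
    grid: WavelengthGrid = DEFAULT_GRID,
    peak: float = 0.72,
    peak_wavelength: float = 550.0,
    sigma_blue: float = 110.0,
    sigma_ir: float = 240.0,
) -> Spectrum:
    """Smooth monochrome-sensor QE: peaks near 550 nm, declines into the IR."""
    lam = grid.wavelengths()
    sigma = np.where(lam < peak_wavelength, sigma_blue, sigma_ir)
    qe = peak * np.exp(-0.5 * ((lam - peak_wavelength) / sigma) ** 2)
    return Spectrum(grid, np.maximum(qe, 1e-4), kind="qe")


def gen_scene(
    height: int,
    width: int,
    n_bands: int = 8,
    kind: str = "cosine",
    seed: int = 0,
    constant: float = 0.25,
    bank: FilterBank | None = None,
):
    """Deterministic multi-band test scene (H x W x n_bands array).

    kinds: ``constant`` (uniform value), ``ramp`` (plane b is
    ``0.1 + 0.02 b + 0.001 x + 0.002 y``), ``cosine`` (band-limited 2-D
    cosines, shortest period 16 px), ``vegetation_patches`` (rectangular
    patches whose band values come from generated reflectances pushed
    through a filter bank).
    """
    if height % 4 or width % 4:
        raise GeometryError(f"scene dims must be divisible by 4, got {height}x{width}")
    if n_bands < 1:
        raise ParameterError("n_bands must be >= 1")
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:height, 0:width].astype(float)

    if kind == "constant":
        return np.full((height, width, n_bands), constant, dtype=float)
    if kind == "ramp":
        cube = np.empty((height, width, n_bands))
        for b in range(n_bands):
            cube[:, :, b] = 0.1 + 0.02 * b + 0.001 * x + 0.002 * y
        return cube
    if kind == "cosine":
        cube = np.empty((height, width, n_bands))
        for b in range(n_bands):
            # shortest per-axis period 32 px: smooth relative to the 4 px
            # sample pitch, so bilinear interpolation stays accurate
            fx = rng.uniform(0.0, 1.0 / 32.0)
            fy = rng.uniform(0.0, 1.0 / 32.0)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.15, 0.3)
            cube[:, :, b] = 0.5 + amp * np.cos(2 * np.pi * (fx * x + fy * y) + phase)
        return cube
    if kind == "vegetation_patches":
        if bank is None:
            from .filters import measured_bank

            bank = measured_bank("VIS")
        from .illuminants import get_illuminant
        from .imaging import camera_response, system_matrix

        params = VegetationModelParams(n_samples=12, n_species=4, seed=seed)
        ds = gen_reflectance_set(params, bank.grid)
        qe = gen_sensor_qe(bank.grid)
        illum = get_illuminant("E", bank.grid)
        A = system_matrix(qe, bank, illum)
        resp = camera_response(A, ds).responses  # n_bands x K
        resp = resp / resp.max()
        if resp.shape[0] != n_bands:
            raise ParameterError("bank size must equal n_bands for vegetation_patches")
        cube = np.full((height, width, n_bands), 0.05)
        for _ in range(10):
            k = rng.integers(0, ds.n_samples)
            y0 = int(rng.integers(0, height))
            x0 = int(rng.integers(0, width))
            h = int(rng.integers(height // 8 + 1, height // 2 + 1))
            w = int(rng.integers(width // 8 + 1, width // 2 + 1))
            cube[y0 : y0 + h, x0 : x0 + w, :] = resp[:, k]
        return cube
    raise ParameterError(f"unknown scene kind {kind!r}")
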