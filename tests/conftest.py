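from pathlib import Path

import numpy as np
import pytest

from msfasim import (
    GASettings,
    Illuminant,
    ReflectanceDataset,
    Spectrum,
    WavelengthGrid,
    gen_reflectance_set,
    gen_sensor_qe,
)
from msfasim.synthetic import VegetationModelParams

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def toy_grid() -> WavelengthGrid:
    """Five points, 400-600 nm at 50 nm."""
    return WavelengthGrid(400.0, 600.0, 50.0)


@pytest.fixture
def coarse_grid() -> WavelengthGrid:
    """41 points, 400-600 nm at 5 nm — cheap GA instances."""
    return WavelengthGrid(400.0, 600.0, 5.0)


@pytest.fixture
def flat_illuminant(toy_grid) -> Illuminant:
    return Illuminant("flat", Spectrum(toy_grid, np.full(5, 1.0), kind="spd"))


def make_flat_illuminant(grid: WavelengthGrid, level: float = 1.0) -> Illuminant:
    return Illuminant(
        "flat", Spectrum(grid, np.full(grid.n_points, level), kind="spd")
    )


def make_flat_qe(grid: WavelengthGrid, level: float = 1.0) -> Spectrum:
    return Spectrum(grid, np.full(grid.n_points, level), kind="qe")


@pytest.fixture
def coarse_dataset(coarse_grid) -> ReflectanceDataset:
    """Small seeded vegetation set on the coarse grid."""
    params = VegetationModelParams(n_samples=30, n_species=4, seed=7, noise_std=0.005)
    return gen_reflectance_set(params, coarse_grid)


@pytest.fixture
def coarse_qe(coarse_grid) -> Spectrum:
    return gen_sensor_qe(coarse_grid)


@pytest.fixture
def fast_settings(coarse_grid) -> GASettings:
    """GA settings sized for sub-second unit-test runs."""
    return GASettings(
        population_size=20,
        max_generations=15,
        bounds=(coarse_grid.start, coarse_grid.stop),
        n_islands=2,
        snr=np.inf,
        seed=0,
    )
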