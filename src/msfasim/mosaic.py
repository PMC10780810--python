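"""Moxel layouts, mosaic simulation, bilinear demosaicking, white calibration.

The repeating unit cell ("moxel") is a 4x4 grid of band indices covering 8
bands twice each; it tiles the sensor ``N_l`` times along lines and ``N_c``
along columns.  Demosaicking reconstructs each band's full-resolution
plane: raw samples are kept exactly, missing pixels are filled by linear
interpolation along rows and columns (averaged where both directions give
an estimate), and pixels reachable by neither direction get a second
interpolation pass over the first-stage result.  Beyond the outermost
samples of a row/column the nearest sample value is extended.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GeometryError, LayoutError, ParameterError

__all__ = [
    "MoxelLayout",
    "RawMosaicImage",
    "SpectralCube",
    "default_layout",
    "load_layout",
    "save_layout",
    "tile_counts",
    "mosaic",
    "demosaic_bilinear",
    "white_calibrate",
    "extract_band_samples",
    "read_raw_image",
    "write_raw_image",
    "read_cube",
    "write_cube",
]

MOXEL_SIZE = 4

#: Default 4x4 pattern: each of 8 bands twice, duplicates offset by
#: (2 rows, 2 columns) for quasi-uniform sampling of every band.
DEFAULT_PATTERN = (
    (0, 1, 2, 3),
    (4, 5, 6, 7),
    (2, 3, 0, 1),
    (6, 7, 4, 5),
)


@dataclass(frozen=True)
class MoxelLayout:
    """4x4 repeating pattern of band indices."""

    pattern: tuple[tuple[int, ...], ...]
    n_bands: int = 8
    which: str = "VIS"
    #: when True (default) every band must appear exactly twice.
    enforce_uniform: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.pattern, dtype=int)
        if arr.shape != (MOXEL_SIZE, MOXEL_SIZE):
            raise LayoutError(f"pattern must be 4x4, got {arr.shape}")
        if arr.min() < 0 or arr.max() >= self.n_bands:
            raise LayoutError(
                f"band indices must lie in 0..{self.n_bands - 1}"
            )
        counts = np.bincount(arr.ravel(), minlength=self.n_bands)
        if np.any(counts == 0):
            missing = np.where(counts == 0)[0].tolist()
            raise LayoutError(f"bands {missing} absent from the pattern")
        if self.enforce_uniform and np.any(counts != MOXEL_SIZE**2 // self.n_bands):
            raise LayoutError(
                f"per-band multiplicity must be {MOXEL_SIZE**2 // self.n_bands}, "
                f"got {counts.tolist()}"
            )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.pattern, dtype=int)

    @property
    def multiplicity(self) -> np.ndarray:
        return np.bincount(self.array.ravel(), minlength=self.n_bands)

    def band_names(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_bands)]


def default_layout(which: str = "VIS") -> MoxelLayout:
    """The documented default layout (identical geometry for VIS and NIR)."""
    key = which.upper()
    if key not in ("VIS", "NIR"):
        raise ParameterError(f"which must be 'VIS' or 'NIR', got {which!r}")
    return MoxelLayout(DEFAULT_PATTERN, n_bands=8, which=key)


def load_layout(path, n_bands: int = 8, which: str = "VIS") -> MoxelLayout:
    """Read a layout file: 4 lines of 4 whitespace-separated integers."""
    lines = [ln.split() for ln in Path(path).read_text().split("\n") if ln.strip()]
    try:
        pattern = tuple(tuple(int(v) for v in row) for row in lines)
    except ValueError as exc:
        raise LayoutError(f"{path}: non-integer entry") from exc
    return MoxelLayout(pattern, n_bands=n_bands, which=which)


def save_layout(layout: MoxelLayout, path) -> None:
    Path(path).write_text(
        "\n".join(" ".join(str(v) for v in row) for row in layout.pattern) + "\n"
    )


@dataclass
class RawMosaicImage:
    """Single-channel mosaicked frame plus the layout that produced it."""

    pixels: np.ndarray
    layout: MoxelLayout

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        h, w = self.pixels.shape
        if h % MOXEL_SIZE or w % MOXEL_SIZE:
            raise GeometryError(f"dims must be divisible by {MOXEL_SIZE}, got {h}x{w}")
        if np.any(self.pixels < 0):
            raise GeometryError("raw pixel values must be >= 0")


@dataclass
class SpectralCube:
    """H x W x n_bands stack of band planes."""

    planes: np.ndarray

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3:
            raise GeometryError("cube must be H x W x n_bands")
        if not np.all(np.isfinite(self.planes)):
            raise GeometryError("cube values must be finite")

    @property
    def n_bands(self) -> int:
        return self.planes.shape[2]


def tile_counts(height: int, width: int, layout: MoxelLayout) -> tuple[int, int]:
    """Number of moxel repetitions along lines and columns."""
    if height % MOXEL_SIZE or width % MOXEL_SIZE:
        raise GeometryError(
            f"image dims must be divisible by {MOXEL_SIZE}, got {height}x{width}"
        )
    return height // MOXEL_SIZE, width // MOXEL_SIZE


def mosaic(cube: SpectralCube, layout: MoxelLayout) -> RawMosaicImage:
    """Sample the cube through the layout: raw[y, x] = cube[y, x, pattern]."""
    h, w, b = cube.planes.shape
    if b != layout.n_bands:
        raise GeometryError(f"cube has {b} bands, layout expects {layout.n_bands}")
    tile_counts(h, w, layout)  # validates divisibility
    pat = layout.array
    band_of_pixel = np.tile(pat, (h // MOXEL_SIZE, w // MOXEL_SIZE))
    yy, xx = np.mgrid[0:h, 0:w]
    raw = cube.planes[yy, xx, band_of_pixel]
    return RawMosaicImage(raw, layout)


def _interp_axis(values: np.ndarray, sampled: np.ndarray, axis: int) -> np.ndarray:
    """1-D linear interpolation of masked samples along ``axis``.

    Lines without any sample come back as NaN; beyond the outermost
    samples of a line the nearest sample value is extended.
    """
    if axis == 0:
        values = values.T
        sampled = sampled.T
    out = np.full_like(values, np.nan, dtype=float)
    idx = np.arange(values.shape[1])
    for i in range(values.shape[0]):
        cols = idx[sampled[i]]
        if cols.size == 0:
            continue
        out[i] = np.interp(idx, cols, values[i, cols])
    return out.T if axis == 0 else out


def demosaic_bilinear(raw: RawMosaicImage) -> SpectralCube:
    """Reconstruct all band planes from a raw mosaic (see module docstring)."""
    h, w = raw.pixels.shape
    layout = raw.layout
    pat = layout.array
    band_of_pixel = np.tile(pat, (h // MOXEL_SIZE, w // MOXEL_SIZE))
    planes = np.empty((h, w, layout.n_bands))
    for b in range(layout.n_bands):
        sampled = band_of_pixel == b
        if not sampled.any():
            raise LayoutError(f"band {b} absent from layout")
        row_est = _interp_axis(raw.pixels, sampled, axis=1)
        col_est = _interp_axis(raw.pixels, sampled, axis=0)
        both = np.isfinite(row_est) & np.isfinite(col_est)
        plane = np.where(
            both,
            0.5 * (row_est + col_est),
            np.where(np.isfinite(row_est), row_est, col_est),
        )
        missing = ~np.isfinite(plane)
        if missing.any():
            # second pass over the first-stage estimates, both directions
            have = np.isfinite(plane)
            row2 = _interp_axis(np.where(have, plane, 0.0), have, axis=1)
            col2 = _interp_axis(np.where(have, plane, 0.0), have, axis=0)
            fill = np.where(
                np.isfinite(row2) & np.isfinite(col2),
                0.5 * (row2 + col2),
                np.where(np.isfinite(row2), row2, col2),
            )
            plane = np.where(missing, fill, plane)
        plane[sampled] = raw.pixels[sampled]  # sampled pixels kept exactly
        planes[:, :, b] = plane
    return SpectralCube(planes)


def white_calibrate(
    cube: SpectralCube, white: SpectralCube, epsilon: float = 1e-6
) -> SpectralCube:
    """Divide a scene cube by a Lambertian-white cube, pixelwise."""
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be > 0, got {epsilon}")
    if cube.planes.shape != white.planes.shape:
        raise GeometryError(
            f"shape mismatch: {cube.planes.shape} vs {white.planes.shape}"
        )
    return SpectralCube(cube.planes / np.maximum(white.planes, epsilon))


def extract_band_samples(
    raw: RawMosaicImage, band: int
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (N x 2, row/col) and values of all pixels of one band."""
    layout = raw.layout
    if not 0 <= band < layout.n_bands:
        raise LayoutError(f"band {band} not in layout (0..{layout.n_bands - 1})")
    h, w = raw.pixels.shape
    band_of_pixel = np.tile(layout.array, (h // MOXEL_SIZE, w // MOXEL_SIZE))
    ys, xs = np.nonzero(band_of_pixel == band)
    coords = np.stack([ys, xs], axis=1)
    return coords, raw.pixels[ys, xs]


# ---------------------------------------------------------------------------
# 16-bit image I/O
# ---------------------------------------------------------------------------


def write_raw_image(raw: RawMosaicImage, path, scale: float | None = None) -> None:
    """Write a raw mosaic as 16-bit single-channel TIFF/PNG."""
    import imageio.v3 as iio

    pixels = raw.pixels
    if scale is None:
        scale = 65535.0 / max(pixels.max(), 1e-12)
    iio.imwrite(Path(path), np.clip(pixels * scale, 0, 65535).astype(np.uint16))


def read_raw_image(path, layout: MoxelLayout, scale: float = 1.0) -> RawMosaicImage:
    import imageio.v3 as iio

    pixels = iio.imread(Path(path)).astype(float) * scale
    return RawMosaicImage(pixels, layout)


def write_cube(cube: SpectralCube, path, scale: float | None = None) -> None:
    """Write a cube as multi-page 16-bit TIFF, page order = band order."""
    import tifffile

    planes = np.moveaxis(cube.planes, 2, 0)
    if scale is None:
        scale = 65535.0 / max(planes.max(), 1e-12)
    tifffile.imwrite(Path(path), np.clip(planes * scale, 0, 65535).astype(np.uint16))


def read_cube(path, scale: float = 1.0) -> SpectralCube:
    import tifffile

    planes = tifffile.imread(Path(path)).astype(float) * scale
    if planes.ndim == 2:
        planes = planes[np.newaxis]
    return SpectralCube(np.moveaxis(planes, 0, 2))
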