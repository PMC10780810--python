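import numpy as np
import pytest

from msfasim import (
    MoxelLayout,
    RawMosaicImage,
    SpectralCube,
    default_layout,
    demosaic_bilinear,
    extract_band_samples,
    gen_scene,
    mosaic,
    tile_counts,
    white_calibrate,
)
from msfasim.errors import GeometryError, LayoutError
from msfasim.mosaic import load_layout, save_layout


def brute_force_demosaic(raw: np.ndarray, pattern: np.ndarray, n_bands: int) -> np.ndarray:
    """Straight-loop reimplementation of the two-pass interpolation rule."""
    h, w = raw.shape
    band_of = np.zeros((h, w), dtype=int)
    for y in range(h):
        for x in range(w):
            band_of[y, x] = pattern[y % 4, x % 4]

    def interp_line(values, positions, length):
        # linear interpolation with nearest-sample extension at the ends
        out = np.full(length, np.nan)
        if not positions:
            return out
        for q in range(length):
            if q <= positions[0]:
                out[q] = values[0]
            elif q >= positions[-1]:
                out[q] = values[-1]
            else:
                for a, b in zip(positions, positions[1:]):
                    if a <= q <= b:
                        t = (q - a) / (b - a)
                        out[q] = (1 - t) * values[positions.index(a)] + t * values[
                            positions.index(b)
                        ]
                        break
        return out

    def directional(source, defined):
        rows = np.full_like(source, np.nan, dtype=float)
        cols = np.full_like(source, np.nan, dtype=float)
        for y in range(h):
            pos = [x for x in range(w) if defined[y, x]]
            rows[y, :] = interp_line([source[y, x] for x in pos], pos, w)
        for x in range(w):
            pos = [y for y in range(h) if defined[y, x]]
            cols[:, x] = interp_line([source[y, x] for y in pos], pos, h)
        merged = np.full_like(rows, np.nan)
        for y in range(h):
            for x in range(w):
                r, c = rows[y, x], cols[y, x]
                if np.isfinite(r) and np.isfinite(c):
                    merged[y, x] = 0.5 * (r + c)
                elif np.isfinite(r):
                    merged[y, x] = r
                elif np.isfinite(c):
                    merged[y, x] = c
        return merged

    cube = np.empty((h, w, n_bands))
    for b in range(n_bands):
        sampled = band_of == b
        stage1 = directional(raw, sampled)
        missing = ~np.isfinite(stage1)
        if missing.any():
            stage2 = directional(np.where(np.isfinite(stage1), stage1, 0.0),
                                 np.isfinite(stage1))
            stage1 = np.where(missing, stage2, stage1)
        stage1[sampled] = raw[sampled]
        cube[:, :, b] = stage1
    return cube


class TestMoxelLayout:
    def test_default_shape_and_multiplicity(self):
        layout = default_layout("VIS")
        assert layout.array.shape == (4, 4)
        assert np.all(layout.multiplicity == 2)

    def test_vis_nir_same_geometry(self):
        assert default_layout("VIS").pattern == default_layout("NIR").pattern
        assert default_layout("NIR").which == "NIR"

    def test_missing_band_rejected(self):
        pattern = tuple(tuple(0 for _ in range(4)) for _ in range(4))
        with pytest.raises(LayoutError):
            MoxelLayout(pattern, n_bands=8)

    def test_uniform_multiplicity_enforced_by_default(self):
        pattern = (
            (0, 1, 2, 3),
            (4, 5, 6, 7),
            (0, 1, 2, 3),
            (4, 5, 6, 0),  # band 0 three times, band 7 once
        )
        with pytest.raises(LayoutError):
            MoxelLayout(pattern, n_bands=8)
        layout = MoxelLayout(pattern, n_bands=8, enforce_uniform=False)
        assert layout.multiplicity[0] == 3 and layout.multiplicity[7] == 1

    def test_wrong_shape(self):
        with pytest.raises(LayoutError):
            MoxelLayout(((0, 1), (2, 3)), n_bands=4)

    def test_file_round_trip(self, tmp_path):
        layout = default_layout("VIS")
        path = tmp_path / "layout.txt"
        save_layout(layout, path)
        assert load_layout(path).pattern == layout.pattern


class TestTileCounts:
    def test_sensor_dimensions(self):
        assert tile_counts(1200, 1600, default_layout("VIS")) == (300, 400)

    def test_single_moxel(self):
        assert tile_counts(4, 4, default_layout("VIS")) == (1, 1)

    def test_non_divisible(self):
        with pytest.raises(GeometryError):
            tile_counts(10, 16, default_layout("VIS"))


class TestMosaic:
    def test_pattern_readout(self):
        layout = default_layout("VIS")
        h, w = 8, 8
        cube = SpectralCube(
            np.stack([np.full((h, w), float(b)) for b in range(8)], axis=2)
        )
        raw = mosaic(cube, layout)
        for y in range(h):
            for x in range(w):
                assert raw.pixels[y, x] == layout.array[y % 4, x % 4]

    def test_constant_cube(self):
        cube = SpectralCube(np.full((8, 8, 8), 0.3))
        assert np.allclose(mosaic(cube, default_layout("VIS")).pixels, 0.3)

    def test_index_arithmetic_oracle(self):
        rng = np.random.default_rng(0)
        cube = SpectralCube(rng.uniform(0, 1, size=(8, 8, 8)))
        layout = default_layout("VIS")
        raw = mosaic(cube, layout)
        for y in range(8):
            for x in range(8):
                b = layout.array[y % 4, x % 4]
                assert raw.pixels[y, x] == cube.planes[y, x, b]

    def test_shape_mismatch(self):
        cube = SpectralCube(np.full((8, 8, 4), 0.3))
        with pytest.raises(GeometryError):
            mosaic(cube, default_layout("VIS"))


class TestDemosaic:
    def test_constant_identity(self):
        layout = default_layout("VIS")
        cube = SpectralCube(np.full((16, 16, 8), 0.7))
        out = demosaic_bilinear(mosaic(cube, layout))
        assert np.allclose(out.planes, 0.7, atol=1e-12)

    def test_sample_preservation(self):
        layout = default_layout("VIS")
        rng = np.random.default_rng(1)
        cube = SpectralCube(rng.uniform(0, 1, size=(12, 12, 8)))
        raw = mosaic(cube, layout)
        out = demosaic_bilinear(raw)
        band_of = np.tile(layout.array, (3, 3))
        for b in range(8):
            mask = band_of == b
            assert np.array_equal(out.planes[:, :, b][mask], raw.pixels[mask])

    def test_matches_brute_force_oracle(self):
        layout = default_layout("VIS")
        rng = np.random.default_rng(2)
        cube = SpectralCube(rng.uniform(0, 1, size=(8, 8, 8)))
        raw = mosaic(cube, layout)
        fast = demosaic_bilinear(raw).planes
        slow = brute_force_demosaic(raw.pixels, layout.array, 8)
        assert np.allclose(fast, slow, atol=1e-12)

    def test_bilinear_planes_exact_in_interior(self):
        layout = default_layout("VIS")
        cube = SpectralCube(gen_scene(16, 16, 8, kind="ramp"))
        out = demosaic_bilinear(mosaic(cube, layout))
        # interior: away from the nearest-extension borders
        err = np.abs(out.planes - cube.planes)[4:-4, 4:-4, :]
        assert err.max() < 1e-12

    def test_smooth_scene_psnr(self):
        layout = default_layout("VIS")
        cube = SpectralCube(gen_scene(64, 64, 8, kind="cosine", seed=11))
        out = demosaic_bilinear(mosaic(cube, layout))
        for b in range(8):
            truth = cube.planes[:, :, b]
            mse = np.mean((out.planes[:, :, b] - truth) ** 2)
            psnr = 10 * np.log10(1.0 / max(mse, 1e-300))
            assert psnr >= 35.0

    def test_translation_equivariance_one_moxel(self):
        layout = default_layout("VIS")
        rng = np.random.default_rng(3)
        big = rng.uniform(0, 1, size=(24, 24, 8))
        cube = SpectralCube(big)
        shifted = SpectralCube(np.roll(big, (4, 4), axis=(0, 1)))
        out = demosaic_bilinear(mosaic(cube, layout)).planes
        out_shifted = demosaic_bilinear(mosaic(shifted, layout)).planes
        # compare away from borders where edge extension differs
        assert np.allclose(
            np.roll(out, (4, 4), axis=(0, 1))[8:-8, 8:-8],
            out_shifted[8:-8, 8:-8],
            atol=1e-12,
        )


class TestWhiteCalibration:
    def test_self_calibration_is_ones(self):
        cube = SpectralCube(np.random.default_rng(0).uniform(0.2, 1, (8, 8, 8)))
        assert np.allclose(white_calibrate(cube, cube).planes, 1.0, atol=1e-12)

    def test_linearity(self):
        white = SpectralCube(np.random.default_rng(0).uniform(0.2, 1, (8, 8, 8)))
        cube = SpectralCube(0.5 * white.planes)
        assert np.allclose(white_calibrate(cube, white).planes, 0.5, atol=1e-12)

    def test_zero_white_guard(self):
        white = SpectralCube(np.zeros((4, 4, 8)))
        cube = SpectralCube(np.full((4, 4, 8), 0.3))
        out = white_calibrate(cube, white, epsilon=1e-3)
        assert np.all(np.isfinite(out.planes))
        assert out.planes.max() <= 0.3 / 1e-3 + 1e-9

    def test_shape_mismatch(self):
        with pytest.raises(GeometryError):
            white_calibrate(
                SpectralCube(np.ones((4, 4, 8))), SpectralCube(np.ones((8, 8, 8)))
            )


class TestExtractBandSamples:
    def test_count_formula(self):
        layout = default_layout("VIS")
        raw = RawMosaicImage(np.zeros((48, 64)), layout)
        coords, values = extract_band_samples(raw, 0)
        n_l, n_c = tile_counts(48, 64, layout)
        assert len(values) == n_l * n_c * layout.multiplicity[0]

    def test_single_moxel(self):
        layout = default_layout("VIS")
        raw = RawMosaicImage(np.arange(16, dtype=float).reshape(4, 4), layout)
        for b in range(8):
            coords, values = extract_band_samples(raw, b)
            assert len(values) == layout.multiplicity[b]

    def test_round_trip_reinsertion(self):
        layout = default_layout("VIS")
        rng = np.random.default_rng(4)
        raw = RawMosaicImage(rng.uniform(0, 1, (8, 8)), layout)
        coords, values = extract_band_samples(raw, 3)
        frame = np.zeros((8, 8))
        frame[coords[:, 0], coords[:, 1]] = values
        again_coords, again_values = extract_band_samples(
            RawMosaicImage(frame, layout), 3
        )
        assert np.array_equal(coords, again_coords)
        assert np.array_equal(values, again_values)

    def test_unknown_band(self):
        raw = RawMosaicImage(np.zeros((4, 4)), default_layout("VIS"))
        with pytest.raises(LayoutError):
            extract_band_samples(raw, 9)


class TestCubeIO:
    def test_cube_tiff_round_trip(self, tmp_path):
        from msfasim.mosaic import read_cube, write_cube

        rng = np.random.default_rng(0)
        cube = SpectralCube(rng.uniform(0, 1, (8, 8, 8)))
        path = tmp_path / "cube.tif"
        write_cube(cube, path, scale=65535.0)
        back = read_cube(path, scale=1.0 / 65535.0)
        assert back.planes.shape == cube.planes.shape
        assert np.allclose(back.planes, cube.planes, atol=1e-4)

    def test_raw_image_round_trip(self, tmp_path):
        from msfasim.mosaic import read_raw_image, write_raw_image

        layout = default_layout("VIS")
        rng = np.random.default_rng(1)
        raw = RawMosaicImage(rng.uniform(0, 1, (8, 8)), layout)
        path = tmp_path / "raw.tiff"
        write_raw_image(raw, path, scale=65535.0)
        back = read_raw_image(path, layout, scale=1.0 / 65535.0)
        assert np.allclose(back.pixels, raw.pixels, atol=1e-4)
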