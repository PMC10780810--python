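# msfasim

Simulation and design toolkit for snapshot multispectral-filter-array
(MSFA) cameras aimed at plant imaging. It covers the full design loop of a
dual-camera (VIS + NIR) eight-band system:

- **Spectral core** — wavelength grids, spectral curve containers,
  resampling, and a CSV dialect for reflectance sets / QE curves / SPDs.
- **Filter model** — peak-normalized Gaussian bandpass transmission
  (`u(λ) = α·exp(−(λ−μ)²/2σ²)`, `σ = FWHM / 2√(2 ln 2)`) and the two
  packaged measured eight-band filter banks (VIS 425–660 nm,
  NIR 670–885 nm).
- **Imaging model** — linear camera forward model (QE × filter ×
  illuminant × Δλ), an SNR-based additive Gaussian noise model, and
  per-band energy balancing.
- **Reconstruction** — Wiener (linear-MMSE) reflectance estimation from
  band responses, plus RMS / GFC / CIEDE2000 metrics with a Table-style
  summary report.
- **Band selection** — a seeded real-coded genetic algorithm (islands,
  migration, tournament selection, elitism, spacing repair) that places
  band centers by minimizing mean Wiener reconstruction RMS, plus an
  exhaustive-search oracle.
- **Mosaic** — 4×4 moxel layouts (8 bands × 2 pixels), mosaic simulation,
  two-pass bilinear demosaicking, Lambertian-white calibration, and
  16-bit TIFF/PNG I/O.
- **Characterization** — simulated monochromator sweeps recovering
  per-band (centering, FWHM, Tmax) from hybrid/bare response ratios.
- **Synthetic data** — seeded generators for vegetation-like reflectance
  datasets (green peak, chlorophyll wells, red edge, NIR plateau, species
  cluster structure), sensor QE curves, and multi-band test scenes.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (Wiener oracle
equivalence, GA vs exhaustive search, the full 626-sample design run,
demosaicking exactness/PSNR, sweep round trips, CIEDE2000 verification
pairs, energy balance).

## CLI

```sh
msfasim gen-data --n-samples 626 --seed 0 --out dataset.csv
msfasim select-bands --dataset dataset.csv --range vis --seed 0 --out centers.csv
msfasim simulate-scene --height 64 --width 64 --kind cosine \
    --cube-out scene.tif --raw-out raw.tif
msfasim demosaic --raw raw.tif --out cube.tif
msfasim characterize --bank VIS --out characterization.csv
msfasim balance --bank NIR --illuminant E --out balance.csv
msfasim run --config config.yaml --out-dir runs/demo
```

`msfasim run` executes a staged pipeline from a YAML config
(`stages: [gen-data, select-bands, simulate-scene, demosaic,
characterize, balance]`, plus `seed`, GA and scene blocks); every artifact
gets a provenance sidecar with the config hash, stage seed and version.

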