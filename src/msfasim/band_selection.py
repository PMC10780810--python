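"""Genetic-algorithm search for filter-band centers, plus a brute-force oracle.

Fitness of a candidate center vector: build a Gaussian bank (fixed FWHM,
unit peak), form the system matrix under the chosen sensor QE and
illuminant, fit the Wiener estimator at the configured noise level,
reconstruct the training reflectances from their (noisy, seeded) band
responses, and return the mean per-sample RMS.  The GA is real-coded with
sorted chromosomes, tournament selection with elitism, blend crossover,
Gaussian mutation, a minimum-spacing repair, and a ring of islands
exchanging migrants at a fixed interval.  All randomness flows from the
settings seed, so identical settings give identical runs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateInputError,
    ParameterError,
    SearchSizeError,
)
from .filters import FilterBank, GaussianFilterSpec
from .imaging import camera_response, noise_std_for_snr, system_matrix
from .reconstruction import (
    ReconstructionReport,
    evaluate,
    fit_wiener,
    reconstruct,
)
from .spectral import Illuminant, ReflectanceDataset, Spectrum

__all__ = [
    "GASettings",
    "BandSelectionResult",
    "fitness",
    "run_ga",
    "exhaustive_search",
    "FitnessEvaluator",
    "RANGE_PRESETS",
]

#: Wavelength-range presets for the two camera designs.
RANGE_PRESETS = {"vis": (380.0, 680.0), "nir": (650.0, 950.0)}


@dataclass(frozen=True)
class GASettings:
    """Genetic-algorithm configuration (defaults follow the design run)."""

    population_size: int = 100
    crossover_fraction: float = 0.6
    migration_fraction: float = 0.2
    fitness_limit: float = 0.02
    n_bands: int = 8
    bounds: tuple[float, float] = (380.0, 680.0)
    fwhm: float = 30.0
    snr: float = 100.0
    max_generations: int = 200
    n_islands: int = 2
    migration_interval: int = 10
    mutation_std: float = 5.0
    min_spacing: float = 10.0
    tournament_size: int = 3
    n_elites: int = 2
    seed: int = 0
    #: optional discrete candidate set; genes snap to the nearest candidate.
    candidate_centers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.crossover_fraction < 1:
            raise ParameterError("crossover_fraction must be in (0, 1)")
        if not 0 <= self.migration_fraction < 1:
            raise ParameterError("migration_fraction must be in [0, 1)")
        if self.population_size < 4:
            raise ParameterError("population_size must be >= 4")
        if self.bounds[0] >= self.bounds[1]:
            raise ParameterError("bounds must be (min, max) with min < max")
        if self.n_bands < 1:
            raise ParameterError("n_bands must be >= 1")
        if self.fwhm <= 0:
            raise ParameterError("fwhm must be > 0")
        if self.snr <= 0:
            raise ParameterError("snr must be > 0")


@dataclass
class BandSelectionResult:
    """Outcome of a band search."""

    centers: np.ndarray
    best_fitness: float
    fitness_history: dict = field(default_factory=dict)
    report: ReconstructionReport | None = None
    terminated_by: str = "max_generations"


class FitnessEvaluator:
    """Caches dataset statistics so repeated fitness calls stay cheap."""

    def __init__(
        self,
        ds: ReflectanceDataset,
        settings: GASettings,
        qe: Spectrum,
        illum: Illuminant,
    ) -> None:
        if ds.n_samples < 1:
            raise DegenerateInputError("dataset is empty")
        if qe.grid != ds.grid or illum.spd.grid != ds.grid:
            raise ParameterError("qe and illuminant must share the dataset grid")
        lo, hi = settings.bounds
        lam = ds.grid.wavelengths()
        if lo < lam[0] - 1e-9 or hi > lam[-1] + 1e-9:
            raise ParameterError("bounds must lie within the dataset grid")
        self.ds = ds
        self.settings = settings
        self.qe = qe
        self.illum = illum
        self._noise_rng_seed = settings.seed  # fixed: fitness is deterministic

    def bank(self, centers: np.ndarray) -> FilterBank:
        specs = [
            GaussianFilterSpec(center=float(c), fwhm=self.settings.fwhm, peak=1.0)
            for c in np.sort(np.asarray(centers, dtype=float))
        ]
        return FilterBank.from_specs(specs, grid=self.ds.grid)

    def __call__(self, centers: np.ndarray) -> float:
        centers = np.asarray(centers, dtype=float)
        lo, hi = self.settings.bounds
        if np.any(centers < lo - 1e-9) or np.any(centers > hi + 1e-9):
            raise ParameterError(
                f"centers {centers} outside bounds [{lo}, {hi}]"
            )
        A = system_matrix(self.qe, self.bank(centers), self.illum)
        O = camera_response(
            A, self.ds, snr=self.settings.snr, seed=self._noise_rng_seed
        )
        noise_var = noise_std_for_snr(A @ self.ds.samples.T, self.settings.snr) ** 2
        est = fit_wiener(A, self.ds, noise_variance=noise_var)
        R_hat = (est.W @ O.responses).T
        err = self.ds.samples - R_hat
        per_sample_rms = np.sqrt(np.mean(err**2, axis=1))
        return float(per_sample_rms.mean())

    def full_report(self, centers: np.ndarray) -> ReconstructionReport:
        A = system_matrix(self.qe, self.bank(centers), self.illum)
        O = camera_response(
            A, self.ds, snr=self.settings.snr, seed=self._noise_rng_seed
        )
        noise_var = noise_std_for_snr(A @ self.ds.samples.T, self.settings.snr) ** 2
        est = fit_wiener(A, self.ds, noise_variance=noise_var)
        ds_hat = reconstruct(est, O, self.ds.grid, labels=list(self.ds.labels))
        return evaluate(self.ds, ds_hat, self.illum)


def fitness(
    centers,
    ds: ReflectanceDataset,
    settings: GASettings,
    qe: Spectrum,
    illum: Illuminant,
) -> float:
    """Mean per-sample reconstruction RMS for one center vector."""
    return FitnessEvaluator(ds, settings, qe, illum)(np.asarray(centers, dtype=float))


# ---------------------------------------------------------------------------
# GA internals
# ---------------------------------------------------------------------------


def _repair(genome: np.ndarray, settings: GASettings) -> np.ndarray:
    """Sort, enforce bounds and minimum spacing, snap to candidates if any."""
    lo, hi = settings.bounds
    g = np.clip(np.sort(np.asarray(genome, dtype=float)), lo, hi)
    spacing = settings.min_spacing
    for i in range(1, g.size):
        if g[i] < g[i - 1] + spacing:
            g[i] = g[i - 1] + spacing
    if g.size and g[-1] > hi:  # push back down from the top
        g[-1] = hi
        for i in range(g.size - 2, -1, -1):
            if g[i] > g[i + 1] - spacing:
                g[i] = g[i + 1] - spacing
        g = np.clip(g, lo, hi)
    if settings.candidate_centers is not None:
        cands = np.sort(np.asarray(settings.candidate_centers, dtype=float))
        chosen: list[int] = []
        for value in g:
            order = np.argsort(np.abs(cands - value))
            for j in order:
                if j not in chosen:
                    chosen.append(int(j))
                    break
        g = np.sort(cands[chosen])
    return g


def _init_population(
    rng: np.random.Generator, settings: GASettings
) -> list[np.ndarray]:
    lo, hi = settings.bounds
    pop = []
    for _ in range(settings.population_size):
        if settings.candidate_centers is not None:
            cands = np.asarray(settings.candidate_centers, dtype=float)
            idx = rng.choice(cands.size, size=settings.n_bands, replace=False)
            genome = cands[idx]
        else:
            genome = rng.uniform(lo, hi, size=settings.n_bands)
        pop.append(_repair(genome, settings))
    return pop


def _tournament(
    rng: np.random.Generator, fits: np.ndarray, k: int
) -> int:
    contenders = rng.integers(0, fits.size, size=k)
    return int(contenders[np.argmin(fits[contenders])])


def _crossover(
    rng: np.random.Generator, p1: np.ndarray, p2: np.ndarray
) -> np.ndarray:
    # blend crossover on the sorted chromosomes
    w = rng.uniform(0.0, 1.0, size=p1.size)
    return w * p1 + (1.0 - w) * p2


def _mutate(
    rng: np.random.Generator, genome: np.ndarray, settings: GASettings
) -> np.ndarray:
    rate = 1.0 / genome.size
    g = genome.copy()
    mask = rng.uniform(size=g.size) < rate
    if not mask.any():  # always perturb at least one gene
        mask[rng.integers(0, g.size)] = True
    g[mask] += rng.normal(0.0, settings.mutation_std, size=int(mask.sum()))
    return g


def _evolve_island(
    rng: np.random.Generator,
    pop: list[np.ndarray],
    fits: np.ndarray,
    evaluator: FitnessEvaluator,
    settings: GASettings,
) -> tuple[list[np.ndarray], np.ndarray]:
    n = len(pop)
    order = np.argsort(fits)
    new_pop: list[np.ndarray] = [pop[i].copy() for i in order[: settings.n_elites]]
    while len(new_pop) < n:
        i = _tournament(rng, fits, settings.tournament_size)
        if rng.uniform() < settings.crossover_fraction:
            j = _tournament(rng, fits, settings.tournament_size)
            child = _crossover(rng, pop[i], pop[j])
        else:
            child = _mutate(rng, pop[i], settings)
        new_pop.append(_repair(child, settings))
    new_fits = np.array([evaluator(g) for g in new_pop])
    return new_pop, new_fits


def run_ga(
    ds: ReflectanceDataset,
    settings: GASettings,
    qe: Spectrum,
    illum: Illuminant,
) -> BandSelectionResult:
    """Search for the center vector minimizing mean reconstruction RMS."""
    evaluator = FitnessEvaluator(ds, settings, qe, illum)
    rng = np.random.default_rng(settings.seed)
    island_size = max(settings.population_size // settings.n_islands, 4)
    islands = [
        _init_population(rng, replace(settings, population_size=island_size))
        for _ in range(settings.n_islands)
    ]
    island_fits = [np.array([evaluator(g) for g in pop]) for pop in islands]

    all_fits0 = np.concatenate(island_fits)
    i0 = int(np.argmin(all_fits0))
    best_fit = float(all_fits0[i0])
    best_genome = [g for pop in islands for g in pop][i0].copy()
    history_best: list[float] = [best_fit]
    history_mean: list[float] = [float(all_fits0.mean())]
    terminated_by = "max_generations"
    if best_fit <= settings.fitness_limit:
        terminated_by = "fitness_limit"

    for generation in range(settings.max_generations if terminated_by != "fitness_limit" else 0):
        for k in range(settings.n_islands):
            islands[k], island_fits[k] = _evolve_island(
                rng, islands[k], island_fits[k], evaluator, settings
            )
        # ring migration of the best migration_fraction individuals
        if (
            settings.n_islands > 1
            and settings.migration_fraction > 0
            and (generation + 1) % settings.migration_interval == 0
        ):
            n_mig = max(1, int(round(settings.migration_fraction * island_size)))
            migrants = []
            for k in range(settings.n_islands):
                order = np.argsort(island_fits[k])
                migrants.append([islands[k][i].copy() for i in order[:n_mig]])
            for k in range(settings.n_islands):
                src = (k - 1) % settings.n_islands
                order = np.argsort(island_fits[k])
                for m, idx in enumerate(order[-n_mig:]):
                    islands[k][idx] = migrants[src][m]
                    island_fits[k][idx] = evaluator(migrants[src][m])

        all_fits = np.concatenate(island_fits)
        gen_best = int(np.argmin(all_fits))
        if all_fits[gen_best] < best_fit:
            best_fit = float(all_fits[gen_best])
            flat = [g for pop in islands for g in pop]
            best_genome = flat[gen_best].copy()
        history_best.append(best_fit)
        history_mean.append(float(all_fits.mean()))
        if best_fit <= settings.fitness_limit:
            terminated_by = "fitness_limit"
            break

    assert best_genome is not None
    centers = np.sort(best_genome)
    return BandSelectionResult(
        centers=centers,
        best_fitness=best_fit,
        fitness_history={"best": history_best, "mean": history_mean},
        report=evaluator.full_report(centers),
        terminated_by=terminated_by,
    )


def exhaustive_search(
    ds: ReflectanceDataset,
    candidate_centers,
    n_bands: int,
    settings: GASettings,
    qe: Spectrum,
    illum: Illuminant,
    cap: int = 20000,
) -> BandSelectionResult:
    """Evaluate every candidate combination; the global-optimum oracle."""
    cands = np.sort(np.asarray(candidate_centers, dtype=float))
    n_comb = math.comb(cands.size, n_bands)
    if n_comb > cap:
        raise SearchSizeError(
            f"{n_comb} combinations exceed the cap of {cap}"
        )
    evaluator = FitnessEvaluator(ds, settings, qe, illum)
    best_fit = math.inf
    best: np.ndarray | None = None
    for combo in itertools.combinations(cands, n_bands):
        centers = np.asarray(combo)
        f = evaluator(centers)
        if f < best_fit:
            best_fit = f
            best = centers
    assert best is not None
    return BandSelectionResult(
        centers=best,
        best_fitness=best_fit,
        report=evaluator.full_report(best),
        terminated_by="exhaustive",
    )
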