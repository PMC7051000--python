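"""Genetic algorithm over SLM phase encodings.

Genomes encode the correction phase either as per-segment 8-bit levels
(piecewise-constant blocks on the control region), as Zernike coefficients
in radians, or as both summed ("mixed").  Evolution is elitist with
rank-weighted parent selection, uniform crossover and a per-gene mutation
rate that decays exponentially over generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .optics import (
    PhaseMask,
    PupilGrid,
    SegmentLayout,
    ZernikeSpec,
    compose,
    segment_phase,
    zernike_phase,
)
from .zernike import zernike_noll

__all__ = [
    "Genome",
    "GenomeSpec",
    "GAConfig",
    "OptimizationTrace",
    "GenomeDecoder",
    "initialize_population",
    "select_parents",
    "crossover",
    "mutate",
    "run_ga",
    "random_search",
    "correction_from_genome",
]

MODES = ("segment", "zernike", "mixed")
DEFAULT_ZERNIKE_MODES = tuple(range(4, 16))  # piston/tip/tilt excluded


@dataclass(eq=False)  # identity semantics; arrays make field-wise eq ambiguous
class Genome:
    """One GA individual: segment levels and/or Zernike coefficients."""

    mode: str
    segment_levels: np.ndarray | None = None
    zernike_coeffs: np.ndarray | None = None
    zernike_modes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode in ("segment", "mixed"):
            if self.segment_levels is None:
                raise ValueError(f"{self.mode} genome requires segment_levels")
            self.segment_levels = np.asarray(self.segment_levels, dtype=np.int64)
            if self.segment_levels.min(initial=0) < 0 or self.segment_levels.max(initial=0) > 255:
                raise ValueError("segment levels must lie in [0, 255]")
        if self.mode in ("zernike", "mixed"):
            if self.zernike_coeffs is None:
                raise ValueError(f"{self.mode} genome requires zernike_coeffs")
            self.zernike_coeffs = np.asarray(self.zernike_coeffs, dtype=float)
            if len(self.zernike_modes) != self.zernike_coeffs.size:
                raise ValueError("zernike_modes and zernike_coeffs length mismatch")

    def copy(self) -> "Genome":
        return Genome(
            self.mode,
            None if self.segment_levels is None else self.segment_levels.copy(),
            None if self.zernike_coeffs is None else self.zernike_coeffs.copy(),
            self.zernike_modes,
        )

    def same_structure(self, other: "Genome") -> bool:
        if self.mode != other.mode or self.zernike_modes != other.zernike_modes:
            return False
        a = 0 if self.segment_levels is None else self.segment_levels.size
        b = 0 if other.segment_levels is None else other.segment_levels.size
        return a == b


@dataclass(frozen=True)
class GenomeSpec:
    """Fixed genome structure for one optimization run."""

    mode: str = "zernike"
    layout: SegmentLayout = field(default_factory=SegmentLayout)
    zernike_modes: tuple[int, ...] = DEFAULT_ZERNIKE_MODES
    init_coeff_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def zero_genome(self) -> Genome:
        seg = (
            np.zeros(self.layout.n_segments, dtype=np.int64)
            if self.mode in ("segment", "mixed")
            else None
        )
        zc = (
            np.zeros(len(self.zernike_modes))
            if self.mode in ("zernike", "mixed")
            else None
        )
        modes = self.zernike_modes if self.mode in ("zernike", "mixed") else ()
        return Genome(self.mode, seg, zc, modes)


@dataclass
class GAConfig:
    """Hyperparameters of the elitist GA.

    Defaults follow common wavefront-shaping practice; the mutation rate
    (and, for Zernike genes, the perturbation scale) decays as
    ``final + (initial - final) * exp(-generation / decay)``.
    """

    population_size: int = 30
    n_generations: int = 300
    n_parents: int = 15
    selection: str = "rank_weighted"
    crossover: str = "uniform_mask"
    mutation_rate_initial: float = 0.1
    mutation_rate_final: float = 0.013
    mutation_decay: float = 60.0
    mutation_scale: float = 0.5
    mutation_scale_final: float | None = 0.05
    elitism: int = 2
    rng_seed: int = 0
    stop_patience: int = 30

    def __post_init__(self) -> None:
        if self.elitism < 1:
            raise ValueError("elitism must be >= 1")
        if self.population_size < 2 * self.elitism:
            raise ValueError("population_size must be >= 2 * elitism")
        if not 1 <= self.n_parents <= self.population_size:
            raise ValueError("n_parents must be in [1, population_size]")
        for r in (self.mutation_rate_initial, self.mutation_rate_final):
            if not 0.0 <= r <= 1.0:
                raise ValueError("mutation rates must lie in [0, 1]")
        if self.mutation_decay <= 0:
            raise ValueError("mutation_decay must be positive")
        if self.selection != "rank_weighted":
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.crossover != "uniform_mask":
            raise ValueError(f"unknown crossover {self.crossover!r}")

    def mutation_rate(self, generation: int) -> float:
        ri, rf = self.mutation_rate_initial, self.mutation_rate_final
        return rf + (ri - rf) * np.exp(-generation / self.mutation_decay)

    def mutation_sigma(self, generation: int) -> float:
        if self.mutation_scale_final is None:
            return self.mutation_scale
        si, sf = self.mutation_scale, self.mutation_scale_final
        return sf + (si - sf) * np.exp(-generation / self.mutation_decay)


@dataclass
class OptimizationTrace:
    """Per-generation fitness history of one run."""

    best: list[float] = field(default_factory=list)
    mean: list[float] = field(default_factory=list)
    sd: list[float] = field(default_factory=list)
    best_genomes: list[Genome] = field(default_factory=list)
    converged: bool = False
    n_evaluations: int = 0

    @property
    def n_generations(self) -> int:
        return len(self.best)

    def to_rows(self) -> list[tuple[int, float, float, float]]:
        return [
            (g, self.best[g], self.mean[g], self.sd[g])
            for g in range(self.n_generations)
        ]


class GenomeDecoder:
    """Fast deterministic genome -> pupil-phase decoding.

    Precomputes the Zernike basis and the segment-block pixel map for a
    grid so the GA inner loop reduces to a matrix product and a gather.
    """

    def __init__(self, spec: GenomeSpec, grid: PupilGrid) -> None:
        self.spec = spec
        self.grid = grid
        if spec.mode in ("zernike", "mixed"):
            rho, theta = grid.unit_coords()
            ap = grid.aperture()
            self._basis = np.stack(
                [zernike_noll(j, rho, theta) * ap for j in spec.zernike_modes]
            ).reshape(len(spec.zernike_modes), -1)
        if spec.mode in ("segment", "mixed"):
            edges = spec.layout.block_edges(grid.n_pixels)
            counts = np.diff(edges)
            s = spec.layout.segments_per_side
            seg_idx = np.arange(s * s).reshape(s, s)
            self._segment_map = np.repeat(
                np.repeat(seg_idx, counts, axis=0), counts, axis=1
            ).ravel()

    def phase_values(self, genome: Genome) -> np.ndarray:
        if genome.mode != self.spec.mode:
            raise ValueError(f"genome mode {genome.mode!r} != spec mode {self.spec.mode!r}")
        n = self.grid.n_pixels
        values = np.zeros(n * n)
        if genome.zernike_coeffs is not None:
            values += genome.zernike_coeffs @ self._basis
        if genome.segment_levels is not None:
            levels = genome.segment_levels.astype(float)
            values += (2.0 * np.pi / 256.0) * levels[self._segment_map]
        return values.reshape(n, n)

    def __call__(self, genome: Genome) -> PhaseMask:
        return PhaseMask(self.phase_values(genome))


def correction_from_genome(
    genome: Genome, layout: SegmentLayout, grid: PupilGrid
) -> PhaseMask:
    """Decode a genome to its correction mask (segment + Zernike parts)."""
    parts: list[PhaseMask] = []
    if genome.segment_levels is not None:
        parts.append(segment_phase(genome.segment_levels, layout, grid))
    if genome.zernike_coeffs is not None:
        spec = ZernikeSpec(dict(zip(genome.zernike_modes, genome.zernike_coeffs)))
        parts.append(zernike_phase(spec, grid))
    if not parts:
        return PhaseMask.zero(grid)
    if len(parts) == 1:
        return parts[0]
    return compose(parts)


def initialize_population(
    config: GAConfig, spec: GenomeSpec, rng: np.random.Generator
) -> list[Genome]:
    """Random first generation; the flat (all-zero) individual is always
    seeded so the optimizer can never end worse than uncorrected."""
    population = [spec.zero_genome()]
    for _ in range(config.population_size - 1):
        seg = zc = None
        modes: tuple[int, ...] = ()
        if spec.mode in ("segment", "mixed"):
            seg = rng.integers(0, 256, size=spec.layout.n_segments)
        if spec.mode in ("zernike", "mixed"):
            zc = rng.normal(0.0, spec.init_coeff_sd, size=len(spec.zernike_modes))
            modes = spec.zernike_modes
        population.append(Genome(spec.mode, seg, zc, modes))
    return population


def select_parents(
    population: list[Genome],
    fitnesses: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
) -> tuple[Genome, Genome]:
    """Rank-weighted draw of two distinct parents from the top n_parents."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if not np.all(np.isfinite(fitnesses)):
        raise ValueError("fitnesses must be finite for selection")
    n_pool = min(config.n_parents, len(population))
    order = np.argsort(fitnesses)[::-1][:n_pool]
    if np.allclose(fitnesses, fitnesses[0]):
        weights = np.full(n_pool, 1.0 / n_pool)
    else:
        ranks = np.arange(n_pool, 0, -1, dtype=float)  # best gets n_pool
        weights = ranks / ranks.sum()
    if n_pool == 1:
        i = j = order[0]
    else:
        i, j = rng.choice(n_pool, size=2, replace=False, p=weights)
        i, j = order[i], order[j]
    return population[i], population[j]


def crossover(
    parent_a: Genome, parent_b: Genome, rng: np.random.Generator
) -> Genome:
    """Uniform crossover: each gene inherited from either parent with p=1/2;
    segment and Zernike parts cross independently."""
    if not parent_a.same_structure(parent_b):
        raise ValueError("parents have mismatched genome structure")
    child = parent_a.copy()
    if child.segment_levels is not None:
        take_b = rng.random(child.segment_levels.size) < 0.5
        child.segment_levels[take_b] = parent_b.segment_levels[take_b]
    if child.zernike_coeffs is not None:
        take_b = rng.random(child.zernike_coeffs.size) < 0.5
        child.zernike_coeffs[take_b] = parent_b.zernike_coeffs[take_b]
    return child


def mutate(
    genome: Genome, generation: int, config: GAConfig, rng: np.random.Generator
) -> Genome:
    """Per-gene mutation: segments resample a uniform level in [0, 255],
    Zernike genes receive a Gaussian kick of the scheduled sigma."""
    if generation < 0:
        raise ValueError("generation must be >= 0")
    rate = config.mutation_rate(generation)
    out = genome.copy()
    if out.segment_levels is not None:
        hit = rng.random(out.segment_levels.size) < rate
        out.segment_levels[hit] = rng.integers(0, 256, size=int(hit.sum()))
    if out.zernike_coeffs is not None:
        hit = rng.random(out.zernike_coeffs.size) < rate
        sigma = config.mutation_sigma(generation)
        out.zernike_coeffs[hit] += rng.normal(0.0, sigma, size=int(hit.sum()))
    return out


def _evaluate(fitness_fn, genome: Genome, index: int) -> float:
    value = float(fitness_fn(genome))
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite fitness {value!r} for genome #{index} (mode={genome.mode})"
        )
    return value


def run_ga(
    fitness_fn, config: GAConfig, spec: GenomeSpec
) -> tuple[Genome, OptimizationTrace]:
    """Elitist evolution loop.

    ``fitness_fn`` maps a :class:`Genome` to a finite scalar to maximize.
    Elites carry their cached fitness forward (they are not re-evaluated),
    so with a noise-free fitness the best recorded value never decreases.
    Returns the best-ever genome and the full trace.
    """
    rng = np.random.default_rng(config.rng_seed)
    population = initialize_population(config, spec, rng)
    fitnesses = np.array(
        [_evaluate(fitness_fn, g, i) for i, g in enumerate(population)]
    )
    trace = OptimizationTrace(n_evaluations=len(population))

    best_idx = int(np.argmax(fitnesses))
    best_genome = population[best_idx].copy()
    best_fitness = float(fitnesses[best_idx])
    since_improvement = 0

    for generation in range(config.n_generations):
        trace.best.append(best_fitness)
        trace.mean.append(float(fitnesses.mean()))
        trace.sd.append(float(fitnesses.std()))
        trace.best_genomes.append(best_genome.copy())

        order = np.argsort(fitnesses)[::-1]
        elites = [population[i].copy() for i in order[: config.elitism]]
        elite_fit = [float(fitnesses[i]) for i in order[: config.elitism]]

        offspring: list[Genome] = []
        for _ in range(config.population_size - config.elitism):
            pa, pb = select_parents(population, fitnesses, config, rng)
            child = mutate(crossover(pa, pb, rng), generation, config, rng)
            offspring.append(child)
        child_fit = [
            _evaluate(fitness_fn, g, i) for i, g in enumerate(offspring)
        ]
        trace.n_evaluations += len(offspring)

        population = elites + offspring
        fitnesses = np.array(elite_fit + child_fit)

        gen_best = int(np.argmax(fitnesses))
        if fitnesses[gen_best] > best_fitness:
            best_fitness = float(fitnesses[gen_best])
            best_genome = population[gen_best].copy()
            since_improvement = 0
        else:
            since_improvement += 1
        if since_improvement >= config.stop_patience:
            trace.converged = True
            break

    trace.best.append(best_fitness)
    trace.mean.append(float(fitnesses.mean()))
    trace.sd.append(float(fitnesses.std()))
    trace.best_genomes.append(best_genome.copy())
    return best_genome, trace


def random_search(
    fitness_fn, n_evaluations: int, spec: GenomeSpec, rng_seed: int
) -> tuple[Genome, float]:
    """Equal-budget baseline: best of i.i.d. draws from the init distribution."""
    rng = np.random.default_rng(rng_seed)
    cfg = replace(GAConfig(), population_size=max(2, n_evaluations), rng_seed=rng_seed)
    candidates = initialize_population(cfg, spec, rng)[:n_evaluations]
    best_g, best_f = None, -np.inf
    for i, g in enumerate(candidates):
        f = _evaluate(fitness_fn, g, i)
        if f > best_f:
            best_g, best_f = g, f
    return best_g, best_f
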