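import numpy as np
import pytest

from sted_ao.ga import (
    GAConfig,
    Genome,
    GenomeDecoder,
    GenomeSpec,
    correction_from_genome,
    crossover,
    initialize_population,
    mutate,
    random_search,
    run_ga,
    select_parents,
)
from sted_ao.microscope import AberrationScreen, GuideStarFitness
from sted_ao.optics import (
    SegmentLayout,
    ZernikeSpec,
    compose,
    segment_phase,
    zernike_phase,
)
from sted_ao.phantoms import ScreenRecipe, make_screen


@pytest.fixture
def seg_spec() -> GenomeSpec:
    return GenomeSpec(mode="segment", layout=SegmentLayout(3))


@pytest.fixture
def zern_spec() -> GenomeSpec:
    return GenomeSpec(mode="zernike", zernike_modes=tuple(range(4, 12)))


class TestGenome:
    def test_segment_genome_length_81(self, seg_spec):
        g = seg_spec.zero_genome()
        assert g.segment_levels.size == 81

    def test_level_bounds_enforced(self):
        with pytest.raises(ValueError):
            Genome("segment", segment_levels=np.array([256]))

    def test_mode_validated(self):
        with pytest.raises(ValueError):
            Genome("annealing")

    def test_zero_genome_decodes_to_zero_mask(self, seg_spec, grid64):
        mask = correction_from_genome(seg_spec.zero_genome(), seg_spec.layout, grid64)
        assert np.all(mask.values == 0)

    def test_pure_zernike_decode_matches_zernike_phase(self, zern_spec, grid64):
        coeffs = np.linspace(-0.5, 0.5, 8)
        g = Genome("zernike", zernike_coeffs=coeffs, zernike_modes=zern_spec.zernike_modes)
        mask = correction_from_genome(g, zern_spec.layout, grid64)
        expected = zernike_phase(
            ZernikeSpec(dict(zip(zern_spec.zernike_modes, coeffs))), grid64
        )
        assert np.allclose(mask.values, expected.values)

    def test_mixed_decode_is_composition(self, grid64):
        layout = SegmentLayout(2)
        levels = np.arange(36) * 7 % 256
        coeffs = np.array([0.3, -0.2])
        g = Genome("mixed", levels, coeffs, (4, 5))
        mask = correction_from_genome(g, layout, grid64)
        expected = compose(
            [
                segment_phase(levels, layout, grid64),
                zernike_phase(ZernikeSpec({4: 0.3, 5: -0.2}), grid64),
            ]
        )
        assert np.allclose(mask.values, expected.values)

    def test_decoder_matches_reference_decode(self, grid64):
        layout = SegmentLayout(2)
        spec = GenomeSpec("mixed", layout, (4, 5, 6))
        rng = np.random.default_rng(0)
        g = Genome(
            "mixed",
            rng.integers(0, 256, 36),
            rng.normal(size=3),
            (4, 5, 6),
        )
        decoder = GenomeDecoder(spec, grid64)
        fast = decoder.phase_values(g)
        slow = segment_phase(g.segment_levels, layout, grid64).values + zernike_phase(
            ZernikeSpec(dict(zip(g.zernike_modes, g.zernike_coeffs))), grid64
        ).values
        assert np.allclose(fast, slow)


class TestInitialization:
    def test_reproducible(self, seg_spec):
        cfg = GAConfig(population_size=4, n_parents=4)
        a = initialize_population(cfg, seg_spec, np.random.default_rng(5))
        b = initialize_population(cfg, seg_spec, np.random.default_rng(5))
        for ga_, gb in zip(a, b):
            assert np.array_equal(ga_.segment_levels, gb.segment_levels)

    def test_flat_individual_seeded_first(self, seg_spec, zern_spec):
        for spec in (seg_spec, zern_spec):
            pop = initialize_population(GAConfig(), spec, np.random.default_rng(0))
            flat = pop[0]
            if flat.segment_levels is not None:
                assert np.all(flat.segment_levels == 0)
            if flat.zernike_coeffs is not None:
                assert np.all(flat.zernike_coeffs == 0)

    def test_population_size_and_bounds(self, seg_spec):
        pop = initialize_population(
            GAConfig(population_size=30), seg_spec, np.random.default_rng(1)
        )
        assert len(pop) == 30
        for g in pop:
            assert g.segment_levels.min() >= 0 and g.segment_levels.max() <= 255


class TestSelection:
    def test_population_of_two_gives_the_single_pair(self, seg_spec):
        pop = initialize_population(
            GAConfig(population_size=2, elitism=1, n_parents=2),
            seg_spec,
            np.random.default_rng(0),
        )
        a, b = select_parents(
            pop, np.array([1.0, 2.0]), GAConfig(population_size=2, elitism=1, n_parents=2),
            np.random.default_rng(0),
        )
        assert {id(a), id(b)} == {id(pop[0]), id(pop[1])}

    def test_rank_weights_match_multinomial_oracle(self, seg_spec):
        cfg = GAConfig(population_size=5, n_parents=5)
        pop = initialize_population(cfg, seg_spec, np.random.default_rng(0))
        fits = np.array([0.1, 0.5, 0.3, 0.9, 0.7])
        rng = np.random.default_rng(123)
        n_draws = 100_000
        counts = np.zeros(5)
        for _ in range(n_draws):
            a, _ = select_parents(pop, fits, cfg, rng)
            counts[pop.index(a)] += 1
        # oracle: first-slot marginal of a weighted draw without replacement
        ranks = {3: 5, 4: 4, 1: 3, 2: 2, 0: 1}  # index -> rank weight
        w = np.array([ranks[i] for i in range(5)], dtype=float)
        w /= w.sum()
        p = counts / n_draws
        sigma = np.sqrt(w * (1 - w) / n_draws)
        assert np.all(np.abs(p - w) < 3.5 * sigma)

    def test_equal_fitness_uniform(self, seg_spec):
        cfg = GAConfig(population_size=4, n_parents=4)
        pop = initialize_population(cfg, seg_spec, np.random.default_rng(0))
        rng = np.random.default_rng(7)
        counts = np.zeros(4)
        for _ in range(20_000):
            a, _ = select_parents(pop, np.ones(4), cfg, rng)
            counts[pop.index(a)] += 1
        assert np.all(np.abs(counts / 20_000 - 0.25) < 0.02)

    def test_best_most_likely(self, seg_spec):
        cfg = GAConfig(population_size=6, n_parents=6)
        pop = initialize_population(cfg, seg_spec, np.random.default_rng(0))
        fits = np.arange(6, dtype=float)
        rng = np.random.default_rng(1)
        counts = np.zeros(6)
        for _ in range(5000):
            a, _ = select_parents(pop, fits, cfg, rng)
            counts[pop.index(a)] += 1
        assert np.argmax(counts) == 5


class TestCrossover:
    def test_identical_parents_give_identical_child(self, seg_spec):
        g = initialize_population(GAConfig(), seg_spec, np.random.default_rng(0))[1]
        child = crossover(g, g.copy(), np.random.default_rng(0))
        assert np.array_equal(child.segment_levels, g.segment_levels)

    def test_every_gene_from_a_parent(self, seg_spec):
        rng = np.random.default_rng(2)
        a, b = initialize_population(GAConfig(), seg_spec, rng)[1:3]
        child = crossover(a, b, rng)
        from_a = child.segment_levels == a.segment_levels
        from_b = child.segment_levels == b.segment_levels
        assert np.all(from_a | from_b)

    def test_inheritance_fraction_binomial_oracle(self):
        layout = SegmentLayout(34)  # 10404 genes > 10^4
        spec = GenomeSpec("segment", layout)
        a = Genome("segment", np.zeros(layout.n_segments, dtype=int))
        b = Genome("segment", np.ones(layout.n_segments, dtype=int))
        child = crossover(a, b, np.random.default_rng(11))
        frac_a = np.mean(child.segment_levels == 0)
        assert abs(frac_a - 0.5) < 0.015

    def test_structure_mismatch_rejected(self, seg_spec, zern_spec):
        a = seg_spec.zero_genome()
        b = zern_spec.zero_genome()
        with pytest.raises(ValueError):
            crossover(a, b, np.random.default_rng(0))


class TestMutation:
    def test_zero_rate_is_identity(self, seg_spec):
        cfg = GAConfig(mutation_rate_initial=0.0, mutation_rate_final=0.0)
        g = initialize_population(cfg, seg_spec, np.random.default_rng(0))[1]
        out = mutate(g, 0, cfg, np.random.default_rng(1))
        assert np.array_equal(out.segment_levels, g.segment_levels)

    def test_full_rate_respects_bounds(self, seg_spec):
        cfg = GAConfig(mutation_rate_initial=1.0, mutation_rate_final=1.0)
        g = seg_spec.zero_genome()
        out = mutate(g, 0, cfg, np.random.default_rng(1))
        assert out.segment_levels.min() >= 0 and out.segment_levels.max() <= 255
        assert np.any(out.segment_levels != g.segment_levels)

    def test_mutation_fraction_binomial_oracle(self):
        layout = SegmentLayout(34)
        cfg = GAConfig(mutation_rate_initial=0.1, mutation_rate_final=0.013)
        g = Genome("segment", np.full(layout.n_segments, 7))
        rng = np.random.default_rng(3)
        n_genes, hits = 0, 0
        for _ in range(10):
            out = mutate(g, 0, cfg, rng)
            changed = out.segment_levels != 7
            # a resampled gene can land on 7 with probability 1/256
            hits += changed.sum()
            n_genes += out.segment_levels.size
        p = cfg.mutation_rate(0) * (1 - 1 / 256)
        sigma = np.sqrt(p * (1 - p) / n_genes)
        assert abs(hits / n_genes - p) < 3.5 * sigma

    def test_rate_schedule_decays(self):
        cfg = GAConfig()
        assert cfg.mutation_rate(0) == pytest.approx(cfg.mutation_rate_initial)
        assert cfg.mutation_rate(10_000) == pytest.approx(cfg.mutation_rate_final)
        rates = [cfg.mutation_rate(g) for g in range(0, 200, 10)]
        assert rates == sorted(rates, reverse=True)


class TestRunGA:
    def test_toy_quadratic_optimum(self):
        # unique optimum at all-100; verify by direct evaluation
        layout = SegmentLayout(1)  # 9 genes
        spec = GenomeSpec("segment", layout)

        def fitness(g):
            return -float(np.sum((g.segment_levels - 100.0) ** 2))

        cfg = GAConfig(
            population_size=20, n_generations=300, n_parents=10,
            stop_patience=300, rng_seed=4,
        )
        best, trace = run_ga(fitness, cfg, spec)
        assert np.all(np.abs(best.segment_levels - 100) <= 12)
        assert trace.best[-1] == fitness(best)

    def test_noise_free_monotonicity(self):
        spec = GenomeSpec("segment", SegmentLayout(1))
        fitness = lambda g: -float(np.sum((g.segment_levels - 50.0) ** 2))
        _, trace = run_ga(fitness, GAConfig(n_generations=60, rng_seed=0), spec)
        best = np.array(trace.best)
        assert np.all(np.diff(best) >= 0)

    def test_bit_reproducible(self):
        spec = GenomeSpec("segment", SegmentLayout(1))
        fitness = lambda g: -float(np.sum((g.segment_levels - 50.0) ** 2))
        cfg = GAConfig(n_generations=40, rng_seed=9)
        b1, t1 = run_ga(fitness, cfg, spec)
        b2, t2 = run_ga(fitness, cfg, spec)
        assert np.array_equal(b1.segment_levels, b2.segment_levels)
        assert t1.best == t2.best and t1.mean == t2.mean

    def test_nonfinite_fitness_aborts_with_diagnostic(self):
        spec = GenomeSpec("segment", SegmentLayout(1))
        with pytest.raises(RuntimeError, match="genome"):
            run_ga(lambda g: float("nan"), GAConfig(n_generations=5), spec)

    def test_patience_stops_early(self):
        spec = GenomeSpec("segment", SegmentLayout(1))
        fitness = lambda g: 1.0  # no improvement possible
        _, trace = run_ga(
            fitness, GAConfig(n_generations=200, stop_patience=10, rng_seed=0), spec
        )
        assert trace.converged
        assert trace.n_generations < 50


class TestConfigValidation:
    def test_population_vs_elitism(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=3, elitism=2)

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            GAConfig(mutation_rate_initial=1.5)


@pytest.mark.slow
class TestOpticalRecovery:
    """GA driving the simulated guide star (smaller grids to stay quick)."""

    def test_defocus_coefficient_recovered(self, grid64):
        # inject a pure-defocus (j=4) screen; the recovered j=4 coefficient
        # must be the negative of the injected one within 0.1 rad
        injected = 1.0
        screen = AberrationScreen(
            zernike_phase(ZernikeSpec({4: injected}), grid64), "system"
        )
        fitness = GuideStarFitness(grid64, screen)
        spec = GenomeSpec("zernike", zernike_modes=(4, 5, 6, 11))
        decoder = GenomeDecoder(spec, grid64)
        best, trace = run_ga(
            lambda g: fitness.from_phase(decoder.phase_values(g)),
            GAConfig(rng_seed=2, n_generations=200),
            spec,
        )
        assert best.zernike_coeffs[0] == pytest.approx(-injected, abs=0.1)
        assert trace.best[-1] > 0.95

    def test_opposite_defocus_gives_opposite_correction(self, grid64):
        corrections = {}
        spec = GenomeSpec("zernike")
        decoder = GenomeDecoder(spec, grid64)
        ap = grid64.aperture().astype(bool)
        for z in (0.5, -0.5):
            screen = make_screen(ScreenRecipe("defocus", defocus_um=z), grid64)
            fitness = GuideStarFitness(grid64, screen)
            best, _ = run_ga(
                lambda g: fitness.from_phase(decoder.phase_values(g)),
                GAConfig(rng_seed=3, n_generations=200),
                spec,
            )
            corrections[z] = decoder.phase_values(best)[ap]
        r = np.corrcoef(corrections[0.5], corrections[-0.5])[0, 1]
        assert r <= -0.9

    def test_coarser_segments_converge_at_least_as_well(self, grid64):
        # fixed budget, fixed screen: 36 segments should do no worse than 144
        screen = make_screen(
            ScreenRecipe("zernike_random", 1.0, (4, 11), rng_seed=1), grid64
        )
        fitness = GuideStarFitness(grid64, screen)
        finals = {}
        for n in (2, 4):  # 36 and 144 segments
            spec = GenomeSpec("segment", SegmentLayout(n))
            decoder = GenomeDecoder(spec, grid64)
            _, trace = run_ga(
                lambda g: fitness.from_phase(decoder.phase_values(g)),
                GAConfig(rng_seed=5, n_generations=120, stop_patience=120),
                spec,
            )
            finals[n] = trace.best[-1]
        assert finals[2] >= finals[4]

    def test_ga_beats_random_search(self, grid64):
        screen = make_screen(
            ScreenRecipe("zernike_random", 1.5, (4, 11), rng_seed=2), grid64
        )
        fitness_obj = GuideStarFitness(grid64, screen)
        spec = GenomeSpec("zernike")
        decoder = GenomeDecoder(spec, grid64)
        fitness = lambda g: fitness_obj.from_phase(decoder.phase_values(g))
        best, trace = run_ga(fitness, GAConfig(rng_seed=6, n_generations=100), spec)
        _, rs_best = random_search(fitness, trace.n_evaluations, spec, rng_seed=6)
        assert trace.best[-1] > rs_best
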