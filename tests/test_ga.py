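"""Genetic-algorithm operators and the full elitist loop."""

import numpy as np
import pytest
from scipy import stats as sps

from recovnet.ga import (
    GAConfig,
    GATrace,
    RealVectorCodec,
    SubsetCodec,
    crossover,
    evaluate,
    fitness_from_loss,
    mutate,
    performance_index,
    performance_index_from,
    run_ga,
    select,
)


class ForcedRng:
    """Minimal rng stub driving deterministic operator branches."""

    def __init__(self, ints=(), floats=()):
        self.ints = list(ints)
        self.floats = list(floats)

    def integers(self, lo, hi=None):
        return self.ints.pop(0)

    def random(self, size=None):
        return self.floats.pop(0)


class TestFitness:
    def test_reciprocal(self):
        assert fitness_from_loss(2) == 0.5
        assert fitness_from_loss(1) == 1.0

    def test_zero_loss_sentinel_ranks_first(self):
        sentinel = fitness_from_loss(0)
        assert sentinel == 2.0
        assert all(sentinel > fitness_from_loss(l) for l in range(1, 50))

    def test_negative_loss_rejected(self):
        with pytest.raises(ValueError):
            fitness_from_loss(-1)

    def test_evaluate_caches_loss(self):
        ch = evaluate(np.array([0.7, 0.2]), lambda g: float((g > 0.5).sum()))
        assert ch.loss == 1.0 and ch.fitness == 1.0


class TestSelect:
    def test_dominant_chromosome_takes_first_slot(self):
        pop = [np.array([float(i)]) for i in range(4)]
        fit = np.array([0.01, 100.0, 0.01, 0.01])
        parents = select(pop, fit, np.random.default_rng(0))
        assert parents[0][0] == 1.0

    def test_eta_two_returns_elite_pair_only(self):
        pop = [np.array([0.0]), np.array([1.0])]
        parents = select(pop, np.array([0.5, 0.9]), np.random.default_rng(0))
        assert len(parents) == 2
        assert parents[0][0] == 1.0 and parents[1][0] == 0.0

    def test_ties_break_by_lower_index(self):
        pop = [np.array([float(i)]) for i in range(3)]
        parents = select(pop, np.array([1.0, 1.0, 0.1]), np.random.default_rng(0))
        assert parents[0][0] == 0.0 and parents[1][0] == 1.0

    def test_equal_fitness_draws_are_uniform(self):
        eta = 10
        pop = [np.array([float(i)]) for i in range(eta)]
        fit = np.ones(eta)
        rng = np.random.default_rng(42)
        counts = np.zeros(eta)
        n_rounds = 10_000 // (eta - 2)
        for _ in range(n_rounds):
            parents = select(pop, fit, rng)
            for p in parents[2:]:
                counts[int(p[0])] += 1
        total = counts.sum()
        chi2 = ((counts - total / eta) ** 2 / (total / eta)).sum()
        assert chi2 < sps.chi2.ppf(0.99, eta - 1)

    def test_all_zero_fitness_uniform_fallback(self):
        pop = [np.array([float(i)]) for i in range(4)]
        parents = select(pop, np.zeros(4), np.random.default_rng(1))
        assert len(parents) == 4


class TestCrossover:
    def test_tail_swap_at_point_two(self):
        p1, p2 = np.zeros(4), np.ones(4)
        o1, o2 = crossover(p1, p2, ForcedRng(ints=[2]))
        assert o1.tolist() == [0, 0, 1, 1]
        assert o2.tolist() == [1, 1, 0, 0]

    def test_identical_parents_yield_parents(self):
        p = np.array([0.1, 0.2, 0.3])
        rng = np.random.default_rng(0)
        for _ in range(5):
            o1, o2 = crossover(p, p.copy(), rng)
            assert np.array_equal(o1, p) and np.array_equal(o2, p)

    def test_gene_multiset_conserved_for_every_point(self):
        rng = np.random.default_rng(3)
        p1, p2 = rng.random(6), rng.random(6)
        for c in range(1, 6):
            o1, o2 = crossover(p1, p2, ForcedRng(ints=[c]))
            assert sorted(np.concatenate([o1, o2])) == pytest.approx(
                sorted(np.concatenate([p1, p2]))
            )

    def test_short_parents_rejected(self):
        with pytest.raises(ValueError):
            crossover(np.array([1.0]), np.array([2.0]), np.random.default_rng(0))


class TestMutate:
    def test_keep_branch_is_identity(self):
        g = np.array([0.1, 0.2, 0.3])
        out = mutate(g, ForcedRng(ints=[1], floats=[0.4]), keep_prob=0.5)
        assert np.array_equal(out, g)

    def test_replace_branch_changes_one_position(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        out = mutate(g, ForcedRng(ints=[2], floats=[0.9, 0.7]), keep_prob=0.5)
        assert out[2] == 0.7
        assert np.array_equal(np.delete(out, 2), np.delete(g, 2))

    def test_at_most_one_gene_differs(self):
        rng = np.random.default_rng(0)
        g = rng.random(8)
        for _ in range(200):
            out = mutate(g, rng)
            assert (out != g).sum() <= 1

    def test_unchanged_fraction_near_half(self):
        rng = np.random.default_rng(1)
        g = rng.random(5)
        unchanged = sum(np.array_equal(mutate(g, rng), g) for _ in range(10_000))
        # binomial 99% CI around 0.5 at n = 10,000
        assert abs(unchanged / 10_000 - 0.5) < 2.576 * 0.005


class TestRunGA:
    def objective(self, genes):
        return float((genes > 0.5).sum())

    def test_reaches_zero_on_small_search_space(self):
        codec = RealVectorCodec(10)
        best, trace = run_ga(self.objective, codec, GAConfig(10, 2000, rng_seed=4))
        assert best.loss == 0
        assert np.all(best.genes <= 0.5)

    def test_zero_generations_returns_initial_best(self):
        codec = RealVectorCodec(6)
        best, trace = run_ga(self.objective, codec, GAConfig(10, 0, rng_seed=0))
        assert trace.generations == 0
        assert best.loss == trace.initial_loss

    def test_best_loss_trace_non_increasing(self):
        for seed in range(3):
            _, trace = run_ga(self.objective, RealVectorCodec(8), GAConfig(10, 200, rng_seed=seed))
            assert np.all(np.diff(trace.best_loss) <= 0)

    def test_population_size_constant(self):
        sizes = []

        def counting_objective(genes):
            sizes.append(len(genes))
            return self.objective(genes)

        run_ga(counting_objective, RealVectorCodec(5), GAConfig(6, 10, rng_seed=0))
        # eta initial evaluations + (eta-2) per generation
        assert len(sizes) == 6 + 4 * 10

    def test_deterministic_given_seed(self):
        cfg = GAConfig(10, 50, rng_seed=77)
        b1, t1 = run_ga(self.objective, RealVectorCodec(8), cfg)
        b2, t2 = run_ga(self.objective, RealVectorCodec(8), cfg)
        assert np.array_equal(b1.genes, b2.genes)
        assert t1.best_loss == t2.best_loss

    def test_zero_mask_genes_stay_zero(self):
        mask = np.array([True, False, True, False, False])
        codec = RealVectorCodec(5, zero_mask=mask)
        best, _ = run_ga(self.objective, codec, GAConfig(4, 100, rng_seed=0))
        assert np.all(best.genes[mask] == 0)

    def test_subset_codec_keeps_distinct_members(self):
        codec = SubsetCodec(12, 4)

        def subset_objective(genes):
            assert len(set(genes.tolist())) == 4
            return float(np.sum(genes))  # prefer low indices

        best, _ = run_ga(subset_objective, codec, GAConfig(6, 200, rng_seed=0))
        assert sorted(best.genes.tolist()) == [0, 1, 2, 3]


class TestPerformanceIndex:
    def test_published_tuning_rows(self):
        assert round(performance_index_from(0.9808, 3.569), 4) == 0.2748
        assert round(performance_index_from(1.0412, 13.021), 2) == 0.08

    def test_simple_ratio(self):
        assert performance_index_from(1, 2) == 0.5

    def test_nonpositive_runtime_rejected(self):
        trace = GATrace(best_loss=[5.0, 3.0], mean_loss=[5.0, 4.0], elapsed_s=[0.0, 0.0])
        with pytest.raises(ValueError):
            performance_index(trace)

    def test_descent_rate_definition(self):
        trace = GATrace(
            best_loss=[10.0, 8.0, 6.0], mean_loss=[10.0, 9.0, 7.0], elapsed_s=[0.1, 0.2, 0.2]
        )
        assert trace.loss_descent_rate == pytest.approx(2.0)
        assert performance_index(trace) == pytest.approx(2.0 / 0.2)
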