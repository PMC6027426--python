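import numpy as np
import pytest

import evostrain as es
from evostrain.encoding import GenomeSpec, Individual, build_value_map
from evostrain.errors import ConfigurationError, DomainError
from evostrain.fitness import FitnessResult
from evostrain.ga_core import (
    GAConfig,
    adaptive_rate,
    crossover,
    generation_step,
    mutate,
    roulette_weights,
    sample_pairs,
    select,
)
from conftest import make_evaluated

SPEC4 = GenomeSpec(ND=4, NI=0, del_scheme=build_value_map(4, 3))


def _pop(NP, L=12, seed=0, fitness=None):
    rng = np.random.default_rng(seed)
    bits = [rng.integers(0, 2, L) for _ in range(NP)]
    f = fitness if fitness is not None else list(rng.random(NP))
    return make_evaluated(bits, f)


def _eval_ones(ind: Individual):
    """Cheap deterministic fitness for operator tests: count of one-bits."""
    if ind.fitness is None:
        f = float(ind.bits.sum())
        ind.fitness = FitnessResult(F=f, F_hat=f, components={}, I=0)
    return ind.fitness


class TestSelect:
    @pytest.mark.parametrize("NP,X,NS,pairs", [
        (20, 0.5, 10, 5),
        (20, 0.25, 4, 8),   # round(5) leaves 15 odd places -> NS adjusted
        (20, 0.75, 14, 3),  # round(15) leaves 5 odd places -> NS adjusted
        (10, 0.25, 2, 4),
    ])
    def test_survivor_count_and_parity(self, NP, X, NS, pairs):
        survivors, state = select(_pop(NP), X)
        assert state.NS == NS == len(survivors)
        assert state.n_pairs == pairs
        assert (NP - NS) % 2 == 0

    def test_survivors_are_fittest_and_fr_recorded(self):
        pop = _pop(10, fitness=[float(i) for i in range(10)])
        survivors, state = select(pop, 0.5)
        fits = sorted((ind.fitness.F_hat for ind in survivors), reverse=True)
        assert fits == [9.0, 8.0, 7.0, 6.0]  # parity adjusts NS 5 -> 4
        assert state.FR == 5.0  # best discarded

    def test_too_few_survivors_rejected(self):
        with pytest.raises(ConfigurationError):
            select(_pop(4), 0.1)

    def test_ties_broken_deterministically(self):
        pop = _pop(8, fitness=[1.0] * 8)
        a, _ = select(pop, 0.5)
        b, _ = select(list(reversed(pop)), 0.5)
        assert [i.key() for i in a] == [i.key() for i in b]


class TestRoulette:
    def test_worked_example(self):
        np.testing.assert_allclose(roulette_weights([3.0, 1.0], 0.0, 0.025),
                                   [0.75, 0.25])

    def test_equal_fitness_gives_uniform(self):
        w = roulette_weights([2.0, 2.0, 2.0, 2.0], 0.0, 0.025)
        np.testing.assert_allclose(w, 0.25)

    def test_zero_fitness_member_gets_floor(self):
        Pmin = 0.025
        w = roulette_weights([0.0, 1.0, 2.0, 3.0], 0.0, Pmin)
        assert w[0] >= Pmin - 1e-12
        assert w.sum() == pytest.approx(1.0)
        assert np.all(np.diff(w) > 0)  # still fitness-ordered

    def test_all_equal_to_discard_falls_back_to_floor_path(self):
        w = roulette_weights([2.0, 2.0], 2.0, 0.05)
        np.testing.assert_allclose(w, 0.5)
        assert w.sum() == pytest.approx(1.0)

    def test_negative_fitness_rejected(self):
        with pytest.raises(DomainError):
            roulette_weights([-1.0, 2.0], 0.0, 0.025)


class TestSamplePairs:
    def test_two_survivors_force_the_single_pair(self, rng):
        pop = _pop(2)
        pairs = sample_pairs(pop, np.array([0.6, 0.4]), 1, rng)
        assert pairs == [(0, 1)] or pairs == [(1, 0)]

    def test_no_duplicate_unordered_pairs(self, rng):
        pop = _pop(6)
        w = np.full(6, 1 / 6)
        pairs = sample_pairs(pop, w, 10, rng)
        unordered = [frozenset(p) for p in pairs]
        assert len(set(unordered)) == 10

    def test_dominant_weight_dominates_pairs(self, rng):
        pop = _pop(4)
        w = np.array([0.9, 0.05, 0.03, 0.02])
        hits = sum(0 in sample_pairs(pop, w, 1, rng)[0] for _ in range(1000))
        assert hits > 950  # P(first not drawn at all) is < 1%

    def test_exhaustion_allows_repeats(self, rng):
        pop = _pop(3)
        w = np.full(3, 1 / 3)
        pairs = sample_pairs(pop, w, 5, rng)  # only 3 distinct pairs exist
        assert len(pairs) == 5


class TestCrossover:
    def test_slotwise_exchange_example(self):
        spec = GenomeSpec(ND=2, NI=0, del_scheme=build_value_map(4, 3))
        p1 = Individual(np.array([0, 0, 0, 0, 0, 0], dtype=np.uint8))
        p2 = Individual(np.array([1, 1, 1, 1, 1, 1], dtype=np.uint8))
        c1, c2 = crossover((p1, p2), spec, np.random.default_rng(0))
        np.testing.assert_array_equal(c1.bits, [0, 0, 0, 1, 1, 1])
        np.testing.assert_array_equal(c2.bits, [1, 1, 1, 0, 0, 0])

    def test_identical_parents_identical_offspring(self, rng):
        p = Individual(rng.integers(0, 2, 12, dtype=np.uint8))
        c1, c2 = crossover((p, p.copy()), SPEC4, rng)
        np.testing.assert_array_equal(c1.bits, p.bits)
        np.testing.assert_array_equal(c2.bits, p.bits)

    def test_slot_multiset_conserved(self, rng):
        for _ in range(50):
            p1 = Individual(rng.integers(0, 2, 12, dtype=np.uint8))
            p2 = Individual(rng.integers(0, 2, 12, dtype=np.uint8))
            c1, c2 = crossover((p1, p2), SPEC4, rng)
            def slots(ind):
                d, _ = SPEC4.slot_values(ind.bits)
                return sorted(d)
            assert sorted(slots(p1) + slots(p2)) == sorted(slots(c1) + slots(c2))

    def test_single_slot_genome_swaps_identity(self, rng):
        spec1 = GenomeSpec(ND=1, NI=0, del_scheme=build_value_map(4, 3))
        p1 = Individual(np.array([0, 1, 0], dtype=np.uint8))
        p2 = Individual(np.array([1, 0, 1], dtype=np.uint8))
        c1, c2 = crossover((p1, p2), spec1, rng)
        np.testing.assert_array_equal(c1.bits, p1.bits)
        np.testing.assert_array_equal(c2.bits, p2.bits)


class TestMutate:
    def test_rate_zero_and_one(self, rng):
        ind = Individual(rng.integers(0, 2, 20, dtype=np.uint8))
        same = mutate(ind, 0.0, rng)
        np.testing.assert_array_equal(same.bits, ind.bits)
        flipped = mutate(ind, 1.0, rng)
        np.testing.assert_array_equal(flipped.bits, 1 - ind.bits)

    def test_elite_is_never_mutated(self, rng):
        ind = Individual(rng.integers(0, 2, 20, dtype=np.uint8))
        ind.fitness = FitnessResult(F=1, F_hat=1, components={}, I=0)
        out = mutate(ind, 1.0, rng, is_elite=True)
        np.testing.assert_array_equal(out.bits, ind.bits)
        assert out.fitness is ind.fitness

    def test_flip_count_matches_binomial(self, rng):
        L, rate, trials = 1000, 0.05, 10_000
        ind = Individual(np.zeros(L, dtype=np.uint8))
        flips = sum(int(mutate(ind, rate, rng).bits.sum())
                    for _ in range(trials))
        mean = trials * L * rate
        sigma = np.sqrt(trials * L * rate * (1 - rate))
        assert abs(flips - mean) < 3 * sigma

    def test_mutation_invalidates_fitness_cache(self, rng):
        ind = Individual(np.zeros(16, dtype=np.uint8))
        ind.fitness = FitnessResult(F=1, F_hat=1, components={}, I=0)
        out = mutate(ind, 1.0, rng)
        assert out.fitness is None


class TestAdaptiveRate:
    def test_endpoints_and_clamping(self):
        assert adaptive_rate(1.0, 1.0, 0.5, 0.01, 0.3) == pytest.approx(0.01)
        assert adaptive_rate(0.5, 1.0, 0.5, 0.01, 0.3) == pytest.approx(0.3)
        assert adaptive_rate(0.2, 1.0, 0.5, 0.01, 0.3) == pytest.approx(0.3)

    def test_degenerate_population_gets_max_rate(self):
        assert adaptive_rate(1.0, 1.0, 1.0, 0.01, 0.3) == 0.3


class TestGenerationStep:
    def _config(self, **kw):
        base = dict(NP=12, X=0.25, R=0.05, ND=4, NC=1, NG=5, NGFE=1, seed=0)
        base.update(kw)
        return GAConfig(**base)

    def test_identical_population_rate_zero_is_fixed_point(self, rng):
        bits = np.ones(12, dtype=np.uint8)
        pop = [Individual(bits.copy()) for _ in range(12)]
        for ind in pop:
            _eval_ones(ind)
        out = generation_step(pop, self._config(R=0.0), SPEC4, _eval_ones, rng)
        assert len(out) == 12
        for ind in out:
            np.testing.assert_array_equal(ind.bits, bits)
            assert ind.fitness.F_hat == 12.0

    @pytest.mark.parametrize("rate", [0.0, 0.05, 0.5])
    def test_elitism_over_random_populations(self, rate):
        cfg = self._config(R=rate)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pop = [Individual(rng.integers(0, 2, 12, dtype=np.uint8))
                   for _ in range(12)]
            for ind in pop:
                _eval_ones(ind)
            before = max(i.fitness.F_hat for i in pop)
            out = generation_step(pop, cfg, SPEC4, _eval_ones, rng)
            after = max(i.fitness.F_hat for i in out)
            assert after >= before

    @pytest.mark.parametrize("NP,X", [(8, 0.25), (12, 0.5), (20, 0.75), (16, 0.3)])
    def test_population_size_restored(self, NP, X, rng):
        pop = [Individual(rng.integers(0, 2, 12, dtype=np.uint8))
               for _ in range(NP)]
        for ind in pop:
            _eval_ones(ind)
        out = generation_step(pop, self._config(NP=NP, X=X), SPEC4,
                              _eval_ones, rng)
        assert len(out) == NP

    def test_adaptive_mode_runs_and_keeps_elite(self, rng):
        cfg = self._config(adaptive=True, Xmin=0.01, Xmax=0.4)
        pop = [Individual(rng.integers(0, 2, 12, dtype=np.uint8))
               for _ in range(12)]
        for ind in pop:
            _eval_ones(ind)
        before = max(i.fitness.F_hat for i in pop)
        out = generation_step(pop, cfg, SPEC4, _eval_ones, rng)
        assert max(i.fitness.F_hat for i in out) >= before


class TestGAConfig:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            GAConfig(X=1.5)
        with pytest.raises(ConfigurationError):
            GAConfig(NP=20, NC=3)  # indivisible; message suggests an NP
        with pytest.raises(ConfigurationError):
            GAConfig(adaptive=True, Xmin=0.5, Xmax=0.1)

    def test_imax_defaults_to_slot_count(self):
        cfg = GAConfig(ND=5, NI=2)
        assert cfg.Imax == 7
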