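from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chisquare

from hfsa.dataset import FeatureMask, SymptomDataset
from hfsa.naive_bayes import FitnessEvaluator
from hfsa.selector import (
    HOAConfig,
    Player,
    binarize,
    bit_flip_mutation,
    exhaustive_oracle,
    ga_generation,
    init_population,
    one_point_crossover,
    roulette_select,
    run_search,
    select_features,
    sigmoid,
    tta_generation,
    update_ball,
    update_player,
)
from tests.conftest import QueuedRng


def constant_players(bits_list, fitnesses):
    return [
        Player.from_mask(FeatureMask(np.array(bits, dtype=np.int8)), fitness=f)
        for bits, f in zip(bits_list, fitnesses)
    ]


class TestInitPopulation:
    def test_contract(self):
        pop = init_population(30, 20, seed=0)
        assert len(pop) == 30
        assert all(p.mask.popcount >= 1 for p in pop)
        assert all(len(p.mask) == 20 for p in pop)

    def test_determinism(self):
        a = init_population(10, 15, seed=3)
        b = init_population(10, 15, seed=3)
        assert all(np.array_equal(x.mask.bits, y.mask.bits) for x, y in zip(a, b))

    def test_bit_frequency_near_half(self):
        pop = init_population(200, 50, seed=1)
        bits = np.vstack([p.mask.bits for p in pop])
        n = bits.size
        se = np.sqrt(0.25 / n)
        assert abs(bits.mean() - 0.5) < 3 * se + 0.01  # +repair bias allowance


class TestRoulette:
    def test_proportional_frequencies(self):
        pop = constant_players([[1, 0], [0, 1]], [1.0, 3.0])
        rng = np.random.default_rng(0)
        picks = np.zeros(2)
        for _ in range(5000):
            a, b = roulette_select(pop, rng, p_sel=1.0)
            picks[int(a.mask.bits[1])] += 1
            picks[int(b.mask.bits[1])] += 1
        freq = picks / picks.sum()
        assert freq[1] == pytest.approx(0.75, abs=0.03)

    def test_equal_fitness_uniform(self):
        pop = constant_players([[1, 0], [0, 1]], [2.0, 2.0])
        rng = np.random.default_rng(1)
        picks = np.zeros(2)
        for _ in range(5000):
            a, _ = roulette_select(pop, rng, p_sel=1.0)
            picks[int(a.mask.bits[1])] += 1
        assert picks[0] / picks.sum() == pytest.approx(0.5, abs=0.03)

    def test_goodness_of_fit_across_seeds(self):
        fitness = [1.0, 2.0, 5.0]
        expected = np.array(fitness) / sum(fitness)
        pop = constant_players([[1, 0, 0], [0, 1, 0], [0, 0, 1]], fitness)
        failures = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = np.zeros(3)
            for _ in range(2000):
                a, b = roulette_select(pop, rng, p_sel=1.0)
                counts[int(np.argmax(a.mask.bits))] += 1
                counts[int(np.argmax(b.mask.bits))] += 1
            p = chisquare(counts, expected * counts.sum()).pvalue
            failures += p < 0.01
        assert failures <= 2  # alpha=0.01 over 20 seeds; allow rare rejections

    def test_zero_fitness_falls_back_uniform(self):
        pop = constant_players([[1, 0], [0, 1]], [0.0, 0.0])
        rng = np.random.default_rng(2)
        a, b = roulette_select(pop, rng, p_sel=1.0)
        assert a is not None and b is not None


class TestCrossover:
    def test_suffix_swap_at_cut_two(self):
        a = FeatureMask(np.array([1, 1, 0, 0]))
        b = FeatureMask(np.array([0, 0, 1, 1]))
        rng = QueuedRng(uniforms=[0.0], ints=[2])  # gate fires, cut after pos 2
        child_a, child_b = one_point_crossover(a, b, p_cross=0.9, rng=rng)
        assert list(child_a.bits) == [1, 1, 1, 1]
        assert list(child_b.bits) == [0, 0, 0, 0]

    def test_gate_off_returns_copies(self):
        a = FeatureMask(np.array([1, 0, 1]))
        b = FeatureMask(np.array([0, 1, 0]))
        rng = np.random.default_rng(0)
        child_a, child_b = one_point_crossover(a, b, p_cross=0.0, rng=rng)
        assert np.array_equal(child_a.bits, a.bits)
        assert np.array_equal(child_b.bits, b.bits)

    def test_locus_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = FeatureMask((rng.random(10) < 0.5).astype(np.int8))
            b = FeatureMask((rng.random(10) < 0.5).astype(np.int8))
            ca, cb = one_point_crossover(a, b, p_cross=1.0, rng=rng)
            for child in (ca, cb):
                ok = (child.bits == a.bits) | (child.bits == b.bits)
                assert ok.all()


class TestMutation:
    def test_gate_off_identity(self):
        mask = FeatureMask(np.array([1, 0, 1]))
        out = bit_flip_mutation(mask, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.bits, mask.bits)

    def test_hamming_distance_when_fired(self):
        rng = np.random.default_rng(1)
        mask = FeatureMask(np.array([1, 0, 1, 1, 0]))
        for _ in range(200):
            out = bit_flip_mutation(mask, 1.0, rng)
            assert int(np.abs(out.bits - mask.bits).sum()) in (1, 2)

    def test_firing_rate(self):
        rng = np.random.default_rng(2)
        mask = FeatureMask(np.array([1, 1, 1, 1]))
        fired = sum(
            not np.array_equal(bit_flip_mutation(mask, 0.01, rng).bits, mask.bits)
            for _ in range(10_000)
        )
        se = np.sqrt(10_000 * 0.01 * 0.99)
        assert abs(fired - 100) < 3 * se

    def test_all_zero_repaired(self):
        mask = FeatureMask(np.array([1, 0]))
        rng = QueuedRng(uniforms=[0.0], ints=[0, 1])  # flips the only 1, then repairs
        out = bit_flip_mutation(mask, 1.0, rng)
        assert out.popcount >= 1


class TestBallAndPlayerUpdates:
    def test_zero_distance_fixed_point(self):
        config = HOAConfig()
        ball = np.array([1.5, -2.0])
        for uniforms in ([0.9, 0.3, 0.3], [0.1, 0.3, 0.3]):  # both branches
            rng = QueuedRng(uniforms=list(uniforms))
            out = update_ball(ball, ball.copy(), config, rng)
            np.testing.assert_allclose(out, ball)

    def test_successful_pass_substitution(self):
        # r=1, ball=2, neighbour=1 -> 1*(2-1) + 2 = 3
        config = HOAConfig(epsilon=0.2)
        rng = QueuedRng(uniforms=[0.9, 0.0])  # rand_p=0.9 > eps; r = 1-0 = 1
        out = update_ball(np.array([2.0]), np.array([1.0]), config, rng)
        assert out[0] == pytest.approx(3.0)

    def test_unsuccessful_pass_substitution(self):
        # C1=1.2, r=0.5 -> 2 - (1.2+0.5)*(2-1) = 0.3
        config = HOAConfig(epsilon=0.2, c1=1.2)
        rng = QueuedRng(uniforms=[0.1, 0.5])  # rand_p=0.1 <= eps; r = 1-0.5
        out = update_ball(np.array([2.0]), np.array([1.0]), config, rng)
        assert out[0] == pytest.approx(0.3)

    def test_player_fixed_point(self):
        config = HOAConfig()
        v = np.array([0.2, -1.0, 3.0])
        rng = np.random.default_rng(0)
        np.testing.assert_allclose(update_player(v, v, v, config, rng), v)

    def test_player_substitution(self):
        # pl=0, ball=1, q=1, r=1, C2=2.5, C3=1 -> 0 + 2.5 + 1 = 3.5
        config = HOAConfig(c2=2.5, c3=1.0)
        rng = QueuedRng(uniforms=[0.0])  # r = 1 - 0 = 1
        out = update_player(np.array([0.0]), np.array([1.0]), np.array([1.0]), config, rng)
        assert out[0] == pytest.approx(3.5)

    def test_player_between_r_limits(self):
        config = HOAConfig(c2=1.5, c3=1.0)
        pl, ball, q = np.array([0.0]), np.array([2.0]), np.array([4.0])
        lo = pl  # r -> 0 limit
        hi = pl + config.c2 * (ball - pl) + config.c3 * (q - pl)  # r = 1
        rng = np.random.default_rng(1)
        for _ in range(100):
            out = update_player(pl, ball, q, config, rng)
            assert lo[0] - 1e-12 <= out[0] <= hi[0] + 1e-12


class TestSigmoidAndBinarize:
    def test_sigmoid_values(self):
        assert sigmoid(0.0) == pytest.approx(0.5)
        assert sigmoid(50.0) > 1 - 1e-9
        for x in (-3.0, -0.5, 2.0):
            assert sigmoid(-x) == pytest.approx(1 - sigmoid(x))

    # companion coordinates at +/-99 keep one bit always on under either rule,
    # so the all-zero repair never perturbs the bit under measurement
    @pytest.mark.parametrize("rule", ["as_printed", "conventional"])
    def test_zero_value_half_frequency(self, rule):
        rng = np.random.default_rng(0)
        hits = sum(
            int(binarize(np.array([0.0, 99.0, -99.0]), rule, rng).bits[0])
            for _ in range(10_000)
        )
        se = np.sqrt(10_000 * 0.25)
        assert abs(hits - 5000) < 3 * se

    def test_saturation_direction(self):
        rng = np.random.default_rng(1)
        printed = [
            int(binarize(np.array([50.0, -50.0]), "as_printed", rng).bits[0])
            for _ in range(200)
        ]
        conventional = [
            int(binarize(np.array([50.0, 0.0]), "conventional", rng).bits[0])
            for _ in range(200)
        ]
        assert sum(printed) == 0
        assert sum(conventional) == 200

    def test_monte_carlo_matches_closed_form(self):
        rng = np.random.default_rng(2)
        trials = 4000
        for value in (-2.0, -0.5, 0.0, 0.7, 1.5):
            expected = 1 - sigmoid(value)
            hits = sum(
                int(binarize(np.array([value, -99.0]), "as_printed", rng).bits[0])
                for _ in range(trials)
            )
            se = np.sqrt(trials * expected * (1 - expected))
            assert abs(hits - trials * expected) < 3 * se + 1

    def test_all_zero_repaired(self):
        rng = np.random.default_rng(3)
        mask = binarize(np.array([99.0, 99.0, 99.0]), "as_printed", rng)
        assert mask.popcount >= 1


class TestGenerations:
    @staticmethod
    def popcount_fitness(mask):
        return mask.popcount / len(mask)

    def test_ga_fixed_point_on_clones(self):
        bits = [1, 1, 0, 1]
        pop = constant_players([bits] * 6, [0.75] * 6)
        config = HOAConfig(pop_size=6, p_mut=0.0)
        out = ga_generation(pop, config, self.popcount_fitness, np.random.default_rng(0))
        assert all(list(p.mask.bits) == bits for p in out)

    def test_ga_elitism_and_size(self):
        rng = np.random.default_rng(1)
        pop = init_population(12, 10, rng=rng)
        for p in pop:
            p.fitness = self.popcount_fitness(p.mask)
        best = max(p.fitness for p in pop)
        config = HOAConfig(pop_size=12)
        for _ in range(50):
            pop = ga_generation(pop, config, self.popcount_fitness, rng)
            assert len(pop) == 12
            new_best = max(p.fitness for p in pop)
            assert new_best >= best
            best = new_best

    def test_tta_single_player_degenerate(self):
        pop = constant_players([[1, 0, 1]], [2 / 3])
        config = HOAConfig(pop_size=2)
        rng = np.random.default_rng(0)
        out = tta_generation(pop, config, self.popcount_fitness, rng)
        assert len(out) == 1
        # its own ball is the neighbour: zero distance leaves the ball unmoved
        np.testing.assert_allclose(out[0].ball, pop[0].ball)

    def test_tta_elitism_monotone(self):
        rng = np.random.default_rng(2)
        pop = init_population(10, 8, rng=rng)
        for p in pop:
            p.fitness = self.popcount_fitness(p.mask)
        config = HOAConfig(pop_size=10)
        best = max(p.fitness for p in pop)
        for _ in range(50):
            pop = tta_generation(pop, config, self.popcount_fitness, rng)
            new_best = max(p.fitness for p in pop)
            assert new_best >= best
            best = new_best

    def test_tta_determinism(self):
        config = HOAConfig(pop_size=8, seed=5)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            pop = init_population(8, 6, rng=rng)
            for p in pop:
                p.fitness = self.popcount_fitness(p.mask)
            pop = tta_generation(pop, config, self.popcount_fitness, rng)
            runs.append(np.vstack([p.mask.bits for p in pop]))
        assert np.array_equal(runs[0], runs[1])


class TestSelectFeatures:
    def test_unique_optimum_found_reliably(self):
        # noiseless planted features: CV accuracy 1.0 is attainable within budget
        from hfsa.synth import GeneratorConfig, generate

        config = GeneratorConfig(
            n_diseases=4,
            n_features=11,
            informative_per_disease=1,
            cases_per_disease=30,
            p_on=1.0,
            p_noise=0.0,
            seed=6,
        )
        ds, truth = generate(config)
        hits = 0
        for seed in range(20):
            res = select_features(
                ds,
                method="hfsa",
                v=10,
                config=HOAConfig(max_it=25, patience=8, seed=seed),
            )
            hits += res.best_fitness >= 1.0 - 1e-12
        assert hits >= 18

    def test_history_non_decreasing(self, small_synth):
        ds, _ = small_synth
        res = select_features(
            ds, method="hfsa", v=15, config=HOAConfig(max_it=12, seed=0)
        )
        assert all(b >= a for a, b in zip(res.history, res.history[1:]))
        assert res.best_fitness == max(res.history)

    @pytest.mark.parametrize("method", ["ga_only", "tta_only"])
    def test_ablations_run(self, small_synth, method):
        ds, _ = small_synth
        res = select_features(
            ds, method=method, v=15, config=HOAConfig(max_it=6, seed=1)
        )
        assert 1 <= res.m <= 15
        assert res.method == method

    def test_hfsa_not_worse_than_ga_only(self, small_synth):
        ds, _ = small_synth
        deltas = []
        for seed in range(5):
            config = HOAConfig(max_it=10, seed=seed)
            hybrid = select_features(ds, method="hfsa", v=15, config=config)
            ga = select_features(ds, method="ga_only", v=15, config=config)
            deltas.append(hybrid.best_fitness - ga.best_fitness)
        assert np.median(deltas) >= -0.02

    def test_full_determinism(self, small_synth):
        ds, _ = small_synth
        config = HOAConfig(max_it=8, seed=11)
        a = select_features(ds, method="hfsa", v=12, config=config)
        b = select_features(ds, method="hfsa", v=12, config=config)
        assert np.array_equal(a.best_mask.bits, b.best_mask.bits)
        assert a.best_fitness == b.best_fitness
        assert a.history == b.history
        assert a.kept_original_indices == b.kept_original_indices

    def test_masks_stay_valid_during_search(self, small_synth):
        ds, _ = small_synth
        seen = []

        def factory(reduced):
            inner = FitnessEvaluator(reduced, seed=0)

            def spy(mask):
                seen.append(mask)
                return inner(mask)

            return spy

        select_features(
            ds,
            method="hfsa",
            v=10,
            config=HOAConfig(max_it=5, seed=2),
            fitness_factory=factory,
        )
        assert seen
        assert all(len(m) == 10 and 1 <= m.popcount <= 10 for m in seen)

    def test_kept_indices_map_through_filter(self, small_synth):
        ds, _ = small_synth
        res = select_features(
            ds, method="hfsa", v=12, config=HOAConfig(max_it=5, seed=3)
        )
        survivors = set(int(i) for i in res.chi_scores.kept_indices)
        assert set(res.kept_original_indices) <= survivors
        assert len(res.kept_original_indices) == res.m


class TestExhaustiveOracle:
    def test_enumeration_count(self):
        calls = []

        def counting(mask):
            calls.append(mask.bits.copy())
            return float(mask.popcount)

        exhaustive_oracle(3, counting)
        assert len(calls) == 7

    def test_oracle_dominates_heuristic(self, small_synth):
        ds, _ = small_synth
        from hfsa.chi2_filter import run_fast_stage

        reduced, _ = run_fast_stage(ds, 8)
        evaluator = FitnessEvaluator(reduced, seed=0)
        _, oracle_fit = exhaustive_oracle(8, evaluator)
        res = run_search(8, HOAConfig(max_it=10, seed=0), evaluator, method="hfsa")
        assert oracle_fit >= res[1] - 1e-12

    def test_refuses_large_space(self):
        with pytest.raises(ValueError):
            exhaustive_oracle(13, lambda m: 0.0)
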