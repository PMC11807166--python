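import numpy as np
import pytest
from scipy.stats import chi2

from gafs import (
    FeatureDataset,
    GAConfig,
    SyntheticSpec,
    chromosome_score,
    crossover,
    fitness,
    generate_dataset,
    initialize_population,
    mrmr_score_vector,
    mutate,
    mutation_prob_at,
    roulette_select,
    run_ga,
    split_dataset,
    weighted_objective,
)
from gafs.errors import EmptySelectionError, GafsError, MissingSplitError
from gafs.filtering import FilterScores
from gafs.ga import k_point_crossover


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(population_size=1),
        dict(crossover_prob=1.2),
        dict(alpha=-0.1),
        dict(min_mutation_prob=0.5, max_mutation_prob=0.1),
        dict(fitness_mode="hybrid"),
        dict(knn_k=0),
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(GafsError):
        GAConfig(**kwargs)


class TestInitialization:
    def test_single_feature_forces_gene_on(self, rng):
        pop = initialize_population(1, GAConfig(population_size=10), rng)
        assert np.all(pop == 1)

    def test_seeded_determinism(self):
        cfg = GAConfig(seed=5)
        a = initialize_population(30, cfg, np.random.default_rng(5))
        b = initialize_population(30, cfg, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_varied_subset_sizes(self, rng):
        cfg = GAConfig(population_size=1000)
        pop = initialize_population(100, cfg, rng)
        assert pop.sum(axis=1).std() > 15  # mixed-Bernoulli spread

    def test_no_empty_chromosomes(self, rng):
        pop = initialize_population(5, GAConfig(population_size=200), rng)
        assert np.all(pop.sum(axis=1) >= 1)


def _scores(vals):
    d = len(vals)
    return FilterScores(
        scores=np.asarray(vals, dtype=float),
        selection_order=np.arange(d),
        relevance=np.asarray(vals, dtype=float),
    )


class TestChromosomeScore:
    def test_mean_over_selected(self):
        s = _scores([2.0, 9.0, 4.0])
        assert chromosome_score(np.array([1, 0, 1]), s) == pytest.approx(3.0)
        assert chromosome_score(np.array([0, 1, 0]), s) == pytest.approx(9.0)
        assert chromosome_score(np.array([1, 1, 1]), s) == pytest.approx(5.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(EmptySelectionError):
            chromosome_score(np.zeros(3, dtype=int), _scores([1.0, 2, 3]))


class TestFitness:
    def test_weighted_objective_arithmetic(self):
        assert weighted_objective(1.0, 100, 100, 0.99) == pytest.approx(0.99)
        assert weighted_objective(0.0, 1, 100, 0.99) == pytest.approx(0.0099)
        assert weighted_objective(0.9, 2, 10, 0.99) == pytest.approx(0.899)

    def test_alpha_default_is_published_value(self):
        assert GAConfig().alpha == 0.99

    def test_filter_mode_bounded(self, planted_ds, rng):
        scores = mrmr_score_vector(planted_ds)
        cfg = GAConfig()
        for _ in range(50):
            c = (rng.random(planted_ds.n_features) < 0.5).astype(np.int8)
            if not c.any():
                c[0] = 1
            f = fitness(c, planted_ds, scores, cfg)
            assert 0.0 <= f <= 1.0

    def test_wrapper_mode_needs_val_split(self):
        ds = generate_dataset(SyntheticSpec(n_samples=60, seed=0))
        scores = mrmr_score_vector(ds)
        c = np.ones(ds.n_features, dtype=np.int8)
        with pytest.raises(MissingSplitError):
            fitness(c, ds, scores, GAConfig(fitness_mode="wrapper"))


class TestRoulette:
    def test_single_member(self, rng):
        assert roulette_select(np.array([0.3]), rng) == 0

    def test_equal_fitnesses_uniform(self, rng):
        counts = np.zeros(4)
        for _ in range(10_000):
            counts[roulette_select(np.ones(4), rng)] += 1
        stat = np.sum((counts - 2500) ** 2 / 2500)
        assert stat < chi2.ppf(0.999, df=3)

    def test_proportional_probabilities(self, rng):
        hits = sum(
            roulette_select(np.array([1.0, 3.0]), rng) == 1 for _ in range(100_000)
        )
        sd = np.sqrt(0.75 * 0.25 * 100_000)
        assert abs(hits - 75_000) < 3 * sd

    def test_handles_nonpositive_fitnesses(self, rng):
        counts = np.zeros(2)
        for _ in range(2000):
            counts[roulette_select(np.array([-1.0, -1.0]), rng)] += 1
        assert counts.min() > 0  # shifted, both reachable

    def test_empty_population_rejected(self, rng):
        with pytest.raises(GafsError):
            roulette_select(np.array([]), rng)


class TestCrossover:
    def test_prob_zero_is_identity(self, rng):
        p1 = np.array([1, 0, 1, 0], dtype=np.int8)
        p2 = np.array([0, 1, 1, 1], dtype=np.int8)
        c1, c2 = crossover(p1, p2, 0.0, rng)
        assert np.array_equal(c1, p1) and np.array_equal(c2, p2)

    def test_prob_one_swaps_everything(self, rng):
        p1 = np.array([1, 0, 1, 0], dtype=np.int8)
        p2 = np.array([0, 1, 1, 1], dtype=np.int8)
        c1, c2 = crossover(p1, p2, 1.0, rng)
        assert np.array_equal(c1, p2) and np.array_equal(c2, p1)

    @pytest.mark.parametrize("prob", [0.2, 0.5, 0.8])
    def test_per_position_conservation(self, prob, rng):
        for _ in range(20):
            p1 = (rng.random(40) < 0.5).astype(np.int8)
            p2 = (rng.random(40) < 0.5).astype(np.int8)
            p1[0] = p2[-1] = 1  # keep repair out of the picture
            c1, c2 = crossover(p1, p2, prob, rng)
            assert np.array_equal(np.sort([c1, c2], axis=0), np.sort([p1, p2], axis=0))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(GafsError):
            crossover(np.ones(3, dtype=np.int8), np.ones(4, dtype=np.int8), 0.5, rng)

    def test_k_point_variant_conserves_positions(self, rng):
        p1 = (rng.random(20) < 0.5).astype(np.int8)
        p2 = 1 - p1
        c1, c2 = k_point_crossover(p1, p2, 2, rng)
        assert np.array_equal(np.sort([c1, c2], axis=0), np.sort([p1, p2], axis=0))


class TestMutation:
    def test_schedule_endpoints_match_published_defaults(self):
        cfg = GAConfig()
        assert mutation_prob_at(0, cfg) == pytest.approx(0.01)
        assert mutation_prob_at(cfg.max_iterations - 1, cfg) == pytest.approx(0.04)

    def test_schedule_midpoint(self):
        cfg = GAConfig(max_iterations=11, min_mutation_prob=0.02,
                       max_mutation_prob=0.06)
        assert mutation_prob_at(5, cfg) == pytest.approx(0.04)

    def test_schedule_single_iteration(self):
        cfg = GAConfig(max_iterations=1)
        assert mutation_prob_at(0, cfg) == pytest.approx(0.01)

    def test_schedule_range_check(self):
        with pytest.raises(GafsError):
            mutation_prob_at(60, GAConfig())

    def test_p_zero_identity_p_one_complement(self, rng):
        g = np.array([1, 0, 0, 1, 0], dtype=np.int8)
        assert np.array_equal(mutate(g, 0.0, rng), g)
        assert np.array_equal(mutate(g, 1.0, rng), 1 - g)

    def test_flip_rate_binomial_concentration(self, rng):
        g = np.zeros(100_000, dtype=np.int8)
        flipped = mutate(g, 0.04, rng).sum()
        sd = np.sqrt(0.04 * 0.96 * 100_000)
        assert abs(flipped - 4000) < 3 * sd


class TestRunGA:
    def test_single_feature_dataset(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 15)
        X = np.column_stack([y + 0.1 * rng.standard_normal(30),
                             rng.standard_normal(30)])
        ds = FeatureDataset(matrix=X[:, :1].repeat(2, axis=1), labels=y)
        # degenerate check with a true 1-feature dataset needs d >= 2 for
        # mRMR, so pass precomputed scores for a single column
        ds1 = FeatureDataset(matrix=X[:, :1], labels=y)
        scores = FilterScores(scores=np.array([3.0]),
                              selection_order=np.array([0]),
                              relevance=np.array([3.0]))
        res = run_ga(ds1, GAConfig(max_iterations=3, seed=0), scores=scores)
        assert np.array_equal(res.best_chromosome, [1])
        assert np.array_equal(res.selected_indices, [0])

    def test_trajectory_monotone_and_consistent(self, planted_ds):
        res = run_ga(planted_ds, GAConfig(max_iterations=15, seed=2))
        assert np.all(np.diff(res.trajectory) >= 0)
        assert res.best_fitness == res.trajectory[-1]
        assert np.array_equal(
            res.selected_indices, np.flatnonzero(res.best_chromosome)
        )
        assert res.evaluations == 15 * 20

    def test_deterministic_per_seed(self, planted_ds):
        cfg = GAConfig(max_iterations=8, seed=42)
        a = run_ga(planted_ds, cfg)
        b = run_ga(planted_ds, cfg)
        assert np.array_equal(a.best_chromosome, b.best_chromosome)
        assert a.trajectory == b.trajectory
        assert a.best_fitness == b.best_fitness

    def test_wrapper_mode_runs_and_selects_subset(self, planted_ds):
        cfg = GAConfig(max_iterations=10, seed=3, fitness_mode="wrapper")
        res = run_ga(planted_ds, cfg)
        assert 1 <= res.selected_indices.size <= planted_ds.n_features
        assert np.all(np.diff(res.trajectory) >= 0)

    def test_extra_noise_feature_cannot_raise_filter_fitness(self, planted_ds):
        """Extending the best chromosome with a pure-noise column lowers the
        sparsity term and cannot lift the capped normalized score."""
        cfg = GAConfig(max_iterations=10, seed=7)
        res = run_ga(planted_ds, cfg)
        base_scores = mrmr_score_vector(planted_ds)
        base_fit = fitness(res.best_chromosome, planted_ds, base_scores, cfg)

        rng = np.random.default_rng(99)
        extended = FeatureDataset(
            matrix=np.column_stack(
                [planted_ds.matrix, rng.standard_normal(planted_ds.n_samples)]
            ),
            labels=planted_ds.labels,
            split_assignment=planted_ds.split_assignment,
        )
        ext_scores = mrmr_score_vector(extended)
        ext_c = np.append(res.best_chromosome, 1)
        assert fitness(ext_c, extended, ext_scores, cfg) <= base_fit
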