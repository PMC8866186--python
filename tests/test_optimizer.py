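"""Feasibility criteria, objective costs, Pareto ranking and annealing search."""

import numpy as np
import pytest

from dgcircuit import (
    ActivityMatrix,
    MetricsReport,
    SimulationSettings,
    evaluate_candidate,
    get_variant,
    ideal_output,
    inclusion_criteria,
    non_dominated_sort,
    objective_costs,
    optimize,
    propose_population,
)

# ---------------------------------------------------------------------------
# brute-force dominance oracle


def dominates(a, b):
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def brute_force_ranks(costs):
    n = len(costs)
    ranks = np.full(n, -1, dtype=int)
    alive = set(range(n))
    rank = 0
    while alive:
        front = [
            i
            for i in alive
            if not any(dominates(costs[j], costs[i]) for j in alive if j != i)
        ]
        for i in front:
            ranks[i] = rank
        alive -= set(front)
        rank += 1
    return ranks


class TestInclusionCriteria:
    def _acts(self, output_values, **extra):
        acts = {"Output": ActivityMatrix(output_values, population="Output")}
        for name, values in extra.items():
            acts[name] = ActivityMatrix(values, population=name)
        return acts

    def test_fully_active_network_is_feasible(self):
        acts = self._acts(np.ones((128, 128)), FF_Inh=np.ones((128, 7)))
        assert inclusion_criteria(acts)

    @pytest.mark.parametrize("n_active,feasible", [(115, False), (116, True)])
    def test_output_unit_threshold_arithmetic(self, n_active, feasible):
        # 115/128 = 89.8% ever-active units fails the 90% rule; 116/128 passes
        values = np.zeros((128, 128))
        values[:, :n_active] = 1.0
        assert inclusion_criteria(self._acts(values)) is feasible

    def test_output_pattern_coverage_threshold(self):
        values = np.ones((128, 128))
        values[: int(128 * 0.2)] = 0.0  # 20% of patterns silent -> < 90% covered
        assert not inclusion_criteria(self._acts(values))

    def test_silent_interneuron_population_is_infeasible(self):
        acts = self._acts(np.ones((128, 128)), FB_Inh=np.zeros((128, 7)))
        assert not inclusion_criteria(acts)

    def test_interneuron_thresholds_are_laxer(self):
        # 6/7 units (85.7%) >= 80% and 60% of patterns is enough for an
        # interneuron population but would fail the output rules
        inh = np.zeros((128, 7))
        inh[:77, :6] = 1.0  # 77/128 = 60.2% of patterns covered
        acts = self._acts(np.ones((128, 128)), FF_Inh=inh)
        assert inclusion_criteria(acts)

    def test_input_population_is_exempt(self, battery7):
        acts = self._acts(np.ones((128, 128)))
        acts["Input"] = battery7.as_activity()  # contains the silent pattern
        assert inclusion_criteria(acts)


class TestObjectiveCosts:
    def test_ideal_output_costs(self, battery7):
        rep = MetricsReport.from_activity(ideal_output(battery7, 128))
        costs = objective_costs([rep])
        assert costs.sparsity_cost == pytest.approx((1 / 128) ** 2)
        assert costs.selectivity_cost == pytest.approx((1 / 128) ** 2)
        assert costs.discriminability_cost == pytest.approx(0.0, abs=1e-15)

    def test_fully_dense_output_costs(self):
        rep = MetricsReport.from_activity(ActivityMatrix(np.ones((16, 16))))
        costs = objective_costs([rep])
        assert costs.sparsity_cost == 1.0
        assert costs.selectivity_cost == 1.0
        assert costs.discriminability_cost == 1.0

    def test_invariant_to_unit_relabeling(self, rng):
        values = rng.uniform(0, 1, size=(16, 12))
        values[values < 0.4] = 0.0
        a = objective_costs([MetricsReport.from_activity(ActivityMatrix(values))])
        b = objective_costs(
            [
                MetricsReport.from_activity(
                    ActivityMatrix(values[:, rng.permutation(12)])
                )
            ]
        )
        assert a.sparsity_cost == pytest.approx(b.sparsity_cost)
        assert a.selectivity_cost == pytest.approx(b.selectivity_cost)
        assert a.discriminability_cost == pytest.approx(b.discriminability_cost)

    def test_costs_average_across_instances(self, rng):
        reps = [
            MetricsReport.from_activity(
                ActivityMatrix(rng.uniform(0, 1, size=(8, 6)))
            )
            for _ in range(3)
        ]
        combined = objective_costs(reps)
        singles = [objective_costs([r]) for r in reps]
        assert combined.sparsity_cost == pytest.approx(
            np.mean([s.sparsity_cost for s in singles])
        )


class TestNonDominatedSort:
    def test_single_model(self):
        assert non_dominated_sort(np.array([[0.1, 0.2, 0.3]])).tolist() == [0]

    def test_strictly_dominated_model_ranks_lower(self):
        ranks = non_dominated_sort(np.array([[0.1, 0.1, 0.1], [0.5, 0.5, 0.5]]))
        assert ranks[0] == 0 and ranks[1] > 0

    def test_incomparable_models_share_the_front(self):
        ranks = non_dominated_sort(np.array([[0.1, 0.9], [0.9, 0.1]]))
        assert ranks.tolist() == [0, 0]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        costs = rng.uniform(0, 1, size=(20, 3))
        # inject duplicates and exact dominations
        costs[5] = costs[2]
        costs[9] = costs[3] + 0.1
        assert np.array_equal(non_dominated_sort(costs), brute_force_ranks(costs))


class TestProposePopulation:
    def test_offspring_respect_bounds(self, rng):
        parents = np.array([[0.011, 0.99], [0.5, 0.02]])
        children = propose_population(parents, 500, 2.0, rng)
        assert children.min() >= 0.01 and children.max() <= 1.0

    def test_zero_temperature_reproduces_parents(self):
        parents = np.array([[0.1, 0.2, 0.3]])
        children = propose_population(parents, 10, 0.0, np.random.default_rng(0))
        assert np.allclose(children, parents[0])

    def test_deterministic_given_seed(self):
        parents = np.random.default_rng(3).uniform(0.01, 1, size=(5, 4))
        a = propose_population(parents, 20, 0.3, np.random.default_rng(42))
        b = propose_population(parents, 20, 0.3, np.random.default_rng(42))
        assert np.array_equal(a, b)


class TestEvaluateCandidate:
    def test_published_lognormal_mean_beats_uniform_models_mean(self, battery7):
        """The tuned log-normal input weight (0.0681) should give a lower
        sparsity cost than re-using the uniform model's mean (0.1135)."""
        variant = get_variant("no-inh-lognormal")
        seeds = [11, 12]
        settings = SimulationSettings()
        tuned = evaluate_candidate(
            variant, seeds, battery7, settings, check_inclusion=False
        )
        detuned = evaluate_candidate(
            variant.with_mean_weights({("Input", "Output"): 0.1135}),
            seeds,
            battery7,
            settings,
            check_inclusion=False,
        )
        assert tuned.sparsity_cost < detuned.sparsity_cost


@pytest.fixture(scope="module")
def tiny_run(battery7):
    return optimize(
        get_variant("no-inh-lognormal"),
        iterations=3,
        population_size=8,
        instances=1,
        seed=5,
        pattern_set=battery7,
    )


class TestOptimize:
    def test_elitism_best_cost_never_increases(self, tiny_run):
        best = tiny_run.best_scalarized_history
        assert np.all(np.diff(best) <= 1e-15)

    def test_parameters_within_bounds(self, tiny_run):
        for rec in tiny_run.history:
            assert rec.params.min() >= 0.01 and rec.params.max() <= 1.0
        assert tiny_run.front_params.min() >= 0.01
        assert tiny_run.front_params.max() <= 1.0

    def test_ranks_match_brute_force_each_iteration(self, tiny_run):
        for rec in tiny_run.history:
            feas = rec.feasible
            if not feas.any():
                assert np.all(rec.ranks == -1)
                continue
            oracle = brute_force_ranks(rec.costs[feas])
            assert np.array_equal(rec.ranks[feas], oracle)
            assert np.all(rec.ranks[~feas] == -1)

    def test_front_is_feasible_and_non_dominated(self, tiny_run):
        assert tiny_run.front_params.shape[0] >= 1
        ranks = non_dominated_sort(tiny_run.front_costs)
        assert np.all(ranks == 0)

    def test_deterministic_given_master_seed(self, battery7):
        kwargs = dict(
            iterations=2,
            population_size=4,
            instances=1,
            seed=9,
            pattern_set=battery7,
        )
        a = optimize(get_variant("no-inh-lognormal"), **kwargs)
        b = optimize(get_variant("no-inh-lognormal"), **kwargs)
        assert np.array_equal(a.front_params, b.front_params)
        assert np.array_equal(a.front_costs, b.front_costs)
        for ra, rb in zip(a.history, b.history):
            assert np.array_equal(ra.params, rb.params)
            assert np.array_equal(ra.costs, rb.costs)

    def test_zero_iterations_evaluates_initial_population_only(self, battery7):
        res = optimize(
            get_variant("no-inh-lognormal"),
            iterations=0,
            population_size=4,
            instances=1,
            seed=5,
            pattern_set=battery7,
        )
        assert len(res.history) == 1
        res1 = optimize(
            get_variant("no-inh-lognormal"),
            iterations=3,
            population_size=4,
            instances=1,
            seed=5,
            pattern_set=battery7,
        )
        # the initial population is identical regardless of iteration count
        assert np.array_equal(res.history[0].params, res1.history[0].params)
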