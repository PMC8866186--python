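"""Multi-objective weight tuning by population-based simulated annealing.

The free parameters of a circuit variant are its per-projection mean
weights, bounded to [0.01, 1]. Each candidate parameter vector is evaluated
by realizing several independent weight instances, presenting the full
combinatorial input battery to each, and scoring the output population on
three objectives — mean squared residual of sparsity, selectivity and
discriminability against their maximum value of 1 — averaged across
instances. Candidates must also satisfy hard inclusion (feasibility)
criteria that forbid trivial solutions which silence units or entire
patterns: for the output population at least 90% of units must be active
for at least one pattern and at least 90% of patterns must activate at
least one unit; every interneuron population needs 80% of units active and
60% of patterns represented.

Each iteration evaluates a population of candidates, ranks the feasible
ones into Pareto fronts by non-dominated sorting, and generates the next
population by perturbing the top-ranked parents multiplicatively in log
parameter space with a scale proportional to a geometrically decaying
annealing temperature. Infeasible candidates receive no rank and produce no
offspring. An elitist archive retains every feasible non-dominated
candidate seen so far, so the best scalarized (summed) cost never
increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import ActivityMatrix
from .dynamics import SimulationSettings, run_battery
from .metrics import MetricsReport
from .patterns import PatternSet, generate_combinatorial_patterns
from .weights import WEIGHT_BOUNDS, VariantConfig, realize_instance

__all__ = [
    "ObjectiveCosts",
    "IterationRecord",
    "OptimizeResult",
    "OptimizationError",
    "inclusion_criteria",
    "objective_costs",
    "non_dominated_sort",
    "propose_population",
    "evaluate_candidate",
    "optimize",
]

#: (min fraction of ever-active units, min fraction of represented patterns)
OUTPUT_INCLUSION = (0.9, 0.9)
INTERNEURON_INCLUSION = (0.8, 0.6)

OBJECTIVE_NAMES = ("sparsity", "selectivity", "discriminability")


class OptimizationError(RuntimeError):
    """Raised when the search cannot find any feasible candidate."""


@dataclass
class ObjectiveCosts:
    """Squared-residual costs vs. the target value 1, averaged over instances."""

    sparsity_cost: float
    selectivity_cost: float
    discriminability_cost: float
    feasible: bool = True

    def as_array(self, include_selectivity: bool = True) -> np.ndarray:
        if include_selectivity:
            return np.array(
                [self.sparsity_cost, self.selectivity_cost, self.discriminability_cost]
            )
        return np.array([self.sparsity_cost, self.discriminability_cost])

    def scalarized(self, include_selectivity: bool = True) -> float:
        return float(self.as_array(include_selectivity).sum())


def inclusion_criteria(
    activities: dict[str, ActivityMatrix],
    output_population: str = "Output",
    output_thresholds: tuple[float, float] = OUTPUT_INCLUSION,
    interneuron_thresholds: tuple[float, float] = INTERNEURON_INCLUSION,
) -> bool:
    """Hard feasibility check on the steady activities of one instance.

    Thresholds are inclusive (>=). Input populations are exempt (their
    activity is clamped); every other non-output population counts as an
    interneuron population.
    """
    if output_population not in activities:
        raise KeyError(f"no {output_population!r} activity matrix supplied")
    for name, act in activities.items():
        if name == "Input":
            continue
        min_units, min_patterns = (
            output_thresholds if name == output_population else interneuron_thresholds
        )
        active = act.active
        frac_units = active.any(axis=0).mean()
        frac_patterns = active.any(axis=1).mean()
        if frac_units < min_units or frac_patterns < min_patterns:
            return False
    return True


def objective_costs(reports: Sequence[MetricsReport]) -> ObjectiveCosts:
    """Mean squared residuals of the three metrics against their maximum (1).

    Sparsity is averaged over patterns, selectivity over units, and
    discriminability over distinct pattern pairs; each cost is then averaged
    across the supplied instances' reports.
    """
    if not reports:
        raise ValueError("need at least one MetricsReport")
    sc = np.mean([np.mean((1.0 - r.sparsity) ** 2) for r in reports])
    se = np.mean([np.mean((1.0 - r.selectivity) ** 2) for r in reports])
    dc = np.mean(
        [np.mean((1.0 - r.discriminability_pairs) ** 2) for r in reports]
    )
    return ObjectiveCosts(float(sc), float(se), float(dc))


def non_dominated_sort(costs: np.ndarray) -> np.ndarray:
    """Pareto ranks by front peeling (rank 0 = non-dominated).

    ``costs`` is an (n_models, n_objectives) array; model a dominates model
    b when it is <= in every objective and < in at least one. Returns an
    integer rank per model.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.ndim != 2:
        raise ValueError("costs must be 2-D (models x objectives)")
    n = costs.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    le = np.all(costs[:, None, :] <= costs[None, :, :], axis=2)
    lt = np.any(costs[:, None, :] < costs[None, :, :], axis=2)
    dominates = le & lt  # dominates[a, b]: a dominates b
    ranks = np.full(n, -1, dtype=int)
    remaining = np.ones(n, dtype=bool)
    rank = 0
    while remaining.any():
        dominated = (dominates & remaining[:, None]).any(axis=0)
        front = remaining & ~dominated
        if not front.any():  # pragma: no cover - impossible for finite costs
            front = remaining
        ranks[front] = rank
        remaining &= ~front
        rank += 1
    return ranks


def propose_population(
    parents: np.ndarray,
    n_offspring: int,
    temperature: float,
    rng: np.random.Generator,
    bounds: tuple[float, float] = WEIGHT_BOUNDS,
) -> np.ndarray:
    """Generate offspring by log-space multiplicative perturbation of parents.

    Each offspring is a uniformly chosen parent times
    ``exp(N(0, temperature))`` per parameter, clipped to ``bounds``; with
    temperature -> 0 offspring coincide with their parents.
    """
    parents = np.atleast_2d(np.asarray(parents, dtype=float))
    idx = rng.integers(0, parents.shape[0], size=n_offspring)
    noise = rng.normal(0.0, max(temperature, 0.0), size=(n_offspring, parents.shape[1]))
    return np.clip(parents[idx] * np.exp(noise), bounds[0], bounds[1])


def evaluate_candidate(
    variant: VariantConfig,
    instance_seeds: Sequence[int],
    pattern_set: PatternSet,
    settings: SimulationSettings,
    output_population: str = "Output",
    check_inclusion: bool = True,
) -> ObjectiveCosts:
    """Simulate all instances of one candidate and score its output metrics."""
    reports = []
    feasible = True
    for seed in instance_seeds:
        instance = realize_instance(variant, int(seed), settings)
        activities = run_battery(instance, pattern_set)
        if check_inclusion and not inclusion_criteria(
            activities, output_population=output_population
        ):
            feasible = False
        reports.append(MetricsReport.from_activity(activities[output_population]))
    costs = objective_costs(reports)
    costs.feasible = feasible
    return costs


@dataclass
class IterationRecord:
    """Everything evaluated during one optimizer iteration."""

    iteration: int
    temperature: float
    params: np.ndarray  # (population_size, n_params)
    costs: np.ndarray  # (population_size, 3)
    feasible: np.ndarray  # (population_size,) bool
    ranks: np.ndarray  # (population_size,) int, -1 for infeasible
    best_scalarized: float  # best archive value after this iteration


@dataclass
class OptimizeResult:
    """Final Pareto front plus full per-iteration history and seeds."""

    variant_name: str
    param_names: tuple[tuple[str, str], ...]
    front_params: np.ndarray
    front_costs: np.ndarray
    history: list[IterationRecord] = field(default_factory=list)
    seed: int | None = None
    instance_seeds: tuple[int, ...] = ()
    include_selectivity: bool = True

    @property
    def best_scalarized_history(self) -> np.ndarray:
        return np.array([rec.best_scalarized for rec in self.history])

    def front_variants(self) -> list[VariantConfig]:
        """Final front as ready-to-simulate variant configurations."""
        return [
            self_variant_with(self.variant_name, self.param_names, p)
            for p in self.front_params
        ]


def self_variant_with(
    name: str, param_names: Sequence[tuple[str, str]], params: np.ndarray
) -> VariantConfig:
    from .weights import get_variant

    return get_variant(name).with_mean_weights(dict(zip(param_names, params)))


def _log_uniform(
    rng: np.random.Generator, shape, bounds: tuple[float, float]
) -> np.ndarray:
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    return np.exp(rng.uniform(lo, hi, size=shape))


def optimize(
    variant: VariantConfig,
    iterations: int = 50,
    population_size: int = 600,
    instances: int = 5,
    seed: int = 0,
    include_selectivity: bool = True,
    check_inclusion: bool = True,
    settings: SimulationSettings | None = None,
    pattern_set: PatternSet | None = None,
    initial_temperature: float = 0.5,
    cooling: float = 0.9,
    parent_fraction: float = 0.2,
    max_restarts: int = 5,
) -> OptimizeResult:
    """Search the per-projection mean weights of ``variant``.

    Full scale is 50 iterations of 600 candidates, each evaluated on all
    2^7 input patterns across 5 independent weight instances; all scales can
    be reduced for desk runs. ``include_selectivity=False`` drops the
    selectivity objective from dominance comparisons (its cost is still
    recorded), and ``check_inclusion=False`` disables the feasibility
    criteria — the two toggles behind the "no selectivity constraint"
    variant are independent. Fully deterministic given ``seed``.

    With ``iterations=0`` the initial population is evaluated once and
    returned without any proposal step.
    """
    settings = settings or SimulationSettings()
    pattern_set = pattern_set or generate_combinatorial_patterns(
        variant.populations()["Input"].size
    )
    param_names = tuple((p.pre, p.post) for p in variant.projections)
    n_params = len(param_names)
    root = np.random.SeedSequence(seed)
    init_ss, prop_ss, inst_ss = root.spawn(3)
    rng_init = np.random.default_rng(init_ss)
    rng_prop = np.random.default_rng(prop_ss)
    # same instance seeds for every candidate: common random numbers make
    # candidate comparisons within and across iterations consistent
    instance_seeds = tuple(
        int(s) % 2**31 for s in inst_ss.generate_state(instances)
    )

    result = OptimizeResult(
        variant_name=variant.name,
        param_names=param_names,
        front_params=np.empty((0, n_params)),
        front_costs=np.empty((0, 3)),
        seed=seed,
        instance_seeds=instance_seeds,
        include_selectivity=include_selectivity,
    )

    population = _log_uniform(rng_init, (population_size, n_params), WEIGHT_BOUNDS)
    # elitist archive entries: (params, active-objective vector, full 3-cost vector)
    archive: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    restarts = 0

    n_generations = max(1, iterations)
    for gen in range(n_generations):
        temperature = initial_temperature * cooling**gen
        cost_objs = []
        for cand in population:
            cand_variant = variant.with_mean_weights(dict(zip(param_names, cand)))
            cost_objs.append(
                evaluate_candidate(
                    cand_variant,
                    instance_seeds,
                    pattern_set,
                    settings,
                    check_inclusion=check_inclusion,
                )
            )
        costs3 = np.array([c.as_array(True) for c in cost_objs])
        feasible = np.array([c.feasible for c in cost_objs])
        objective = np.array(
            [c.as_array(include_selectivity) for c in cost_objs]
        )
        ranks = np.full(population.shape[0], -1, dtype=int)
        if feasible.any():
            ranks[feasible] = non_dominated_sort(objective[feasible])
        # elitist archive of feasible candidates, re-peeled each iteration
        for p, obj, c3, ok in zip(population, objective, costs3, feasible):
            if ok:
                archive.append((p.copy(), obj, c3))
        if archive:
            keep = non_dominated_sort(np.array([e[1] for e in archive])) == 0
            archive = [e for e, k in zip(archive, keep) if k]
            best = min(float(e[1].sum()) for e in archive)
        else:
            best = np.inf
        result.history.append(
            IterationRecord(
                iteration=gen,
                temperature=temperature,
                params=population.copy(),
                costs=costs3,
                feasible=feasible,
                ranks=ranks,
                best_scalarized=best,
            )
        )
        if gen == n_generations - 1 or iterations == 0:
            break
        if feasible.any():
            restarts = 0
            scalarized = objective.sum(axis=1)
            order = np.lexsort(
                (np.arange(population.shape[0]), scalarized, ranks)
            )
            order = order[feasible[order]]
            n_parents = max(1, min(order.size, int(round(parent_fraction * population_size))))
            parents = population[order[:n_parents]]
            population = propose_population(
                parents, population_size, temperature, rng_prop
            )
        else:
            restarts += 1
            if restarts > max_restarts:
                raise OptimizationError(
                    f"no feasible candidates after {restarts} consecutive "
                    f"restarts (variant {variant.name!r}, seed {seed})"
                )
            population = _log_uniform(
                rng_prop, (population_size, n_params), WEIGHT_BOUNDS
            )

    if archive:
        # the front is reported with full 3-cost vectors for transparency;
        # dominance was computed on the active objectives only
        result.front_params = np.array([e[0] for e in archive])
        result.front_costs = np.array([e[2] for e in archive])
    return result
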