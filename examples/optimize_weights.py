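"""A desk-scale run of the multi-objective weight search.

Tunes the three mean weights of the feedforward-inhibition circuit with
population-based simulated annealing: each candidate is scored on sparsity,
selectivity and discriminability residuals, infeasible candidates (silenced
units or patterns) are discarded, and survivors are ranked into Pareto
fronts. The full-scale procedure uses 50 iterations x 600 candidates x 5
instances; here everything is scaled down to finish in under a minute.
"""

from dgcircuit import get_variant, optimize

result = optimize(
    get_variant("ff-inh"),
    iterations=4,
    population_size=12,
    instances=1,
    seed=3,
)

print("best summed cost per iteration:",
      [f"{c:.4f}" for c in result.best_scalarized_history])
print(f"final Pareto front: {result.front_params.shape[0]} candidate(s)")
for params, costs in zip(result.front_params, result.front_costs):
    named = ", ".join(
        f"{pre}->{post}: {w:.3f}"
        for (pre, post), w in zip(result.param_names, params)
    )
    print(f"  [{named}]  costs (sp, sel, disc) = "
          f"({costs[0]:.4f}, {costs[1]:.4f}, {costs[2]:.4f})")
# lower costs are better (squared residuals against the ideal value 1);
# the best-so-far cost can only decrease thanks to the elitist archive
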