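# Methods

This note documents the model, the numerical choices and the design
decisions behind `dgcircuit`, and states what the tests do and do not
establish.

## Circuit model

Networks are built from named cell populations. The standard parameter set
(`default_populations`) mirrors the dentate gyrus-inspired configuration
shared by all catalog variants:

| population | units | tau_cell (s) | syn tau_rise (s) | syn tau_decay (s) | syn E_rev (mV) |
|---|---|---|---|---|---|
| Input   | 7   | — (clamped) | 0.001 | 0.01 | +60 |
| Output  | 128 | 0.05        | 0.001 | 0.01 | +60 |
| FF_Inh  | 7   | 0.02        | 0.001 | 0.02 | -10 |
| FB_Inh  | 7   | 0.02        | 0.001 | 0.02 | -10 |
| FB_Exc  | 7   | 0.05        | 0.001 | 0.01 | +60 |

Synaptic kinetics and reversal potential attach to the **presynaptic**
population: all synapses made by a unit share them. Connectivity between
connected populations is all-to-all; recurrent projections exclude
autapses by default (a toggle exists), and after zeroing the diagonal the
remaining entries are rescaled so the mean over actual synapses equals the
requested mean.

Membrane dynamics are leaky integration of conductance-based synaptic
current, `tau_cell dV/dt = -V + IR` with
`I_i = sum_j w_ij g_ij (E_j - V_i)`. The input resistance `R` is
dimensionless and fixed at 1: the published weight scale only makes sense
with `R` folded into the weights, so the package treats `R` as a pure
convention (exposed in `SimulationSettings` for completeness). Voltages
are bounded by construction between the inhibitory reversal (-10 mV) and
the excitatory reversal (+60 mV); activity is piecewise linear between the
+10 mV threshold and +60 mV.

Conductances obey `dg/dt = -g/tau_decay + max(a_pre - g, 0)/tau_rise`,
saturating at the presynaptic activity. Because a conductance state
depends only on its source unit's activity and the source population's
shared kinetics, with identical initial conditions every target of a given
unit sees exactly the same conductance; the integrator therefore carries
**one conductance state per presynaptic unit** instead of one per synapse.
This is an exact reduction, not an approximation.

## Simulation protocol and numerics

Each binary pattern is presented for 0.35 s with input activities clamped
to the pattern bits; all other states start from rest (V = 0 mV, g = 0).
Steady activity is the time average over the final 0.2 s. Rather than
sampling the trajectory, the battery runner appends accumulator states
`dA/dt = activity(V)` over the averaging window (integrated as a second
leg starting at 0.15 s) so the reported steady activity is the solver's
exact window integral divided by the window length.

The ODE system is non-stiff but non-smooth (the `max` in the conductance
kinetics and the activation clipping introduce kinks); it is integrated
with an adaptive Runge-Kutta 4(5) scheme at `rtol = 1e-6`, `atol = 1e-8`.
Halving the tolerances moves steady activities by less than `1e-4`
(tested). All patterns of a battery are integrated as one block-diagonal
system: the dynamics of different patterns never couple, only the adaptive
step sequence is shared, which changes results within solver tolerance
only. Recorded traces are interpolated on a 1 ms grid; the dense
interpolant can overshoot zero by ~1e-5 on decaying conductances, which is
why bound checks in the tests carry a small tolerance.

Downstream of the simulator, "nonzero activity" means activity greater
than `1e-6` (`ACTIVITY_EPS`): the metric definitions are set-membership
statements on exact zeros, which is unsafe in floating point. The
threshold-linear activation makes true zeros common, so the guard only
protects against solver noise.

## Metrics

Population sparsity, unit selectivity and pairwise discriminability are
defined in the README. Degenerate cases score zero rather than one —
a silent population is *not* sparse, a silent unit is *not* selective and
a silenced pattern is *not* discriminable — so the metrics cannot be gamed
by shutting the network down. Cross-condition comparisons use two-sample
two-sided Kolmogorov-Smirnov tests on distributions pooled across network
instances, with Bonferroni adjustment by the number of panel comparisons
(the pooling choice is exposed; per-instance comparison is possible by
calling `compare_distributions` on individual reports). Cumulative
distributions across instances are evaluated on a fixed grid of 513 points
(steps of 1/512) so the mean and standard deviation across instances are
well defined.

## Weight distributions

Uniform projections sample `U(0, 2*mean)`. "Log-normal" projections sample
`exp(N(0, 1))` and rescale the whole draw multiplicatively so the realized
sample mean equals the requested mean *exactly* — the published
description ("the natural log of a random normal variable") is undefined
for negative draws, and the standard log-normal matches the intended
right-skewed, strictly positive distribution. Each (instance, projection)
pair derives its RNG from a stable sub-seed (`SeedSequence(instance_seed,
spawn_key=(crc32("pre->post"),))`), so adding or removing a projection
never perturbs the draws of the others.

The nine-variant catalog carries the published tuned mean weights as fixed
inputs. The excitatory→excitatory ⇒ log-normal rule is the default
assignment; the `no-inh-uniform` variant is the deliberate control that
overrides it on its single projection.

## Optimization

The per-projection mean weights are searched within [0.01, 1] by a
population-based multi-objective annealing procedure: per iteration a
population of candidates is evaluated (all 128 patterns × several weight
instances each), feasible candidates are ranked into Pareto fronts, and
offspring are generated from the top-ranked parents. Objectives are the
mean squared residuals of output sparsity, selectivity and
discriminability against their maximum value 1, averaged across instances
(mean rather than sum keeps costs comparable across population sizes and
is rank-neutral under dominance). Feasibility requires ≥90% of output
units ever active and ≥90% of patterns represented, and ≥80% / ≥60% for
every interneuron population; a candidate must satisfy the criteria in
**every** evaluated instance (the stricter of the two readings, chosen for
determinism). Infeasible candidates receive no rank and no offspring.

Choices the published description leaves open, fixed here: initial
candidates are log-uniform over the bounds; proposals multiply a uniformly
chosen parent by `exp(N(0, T))` per parameter with temperature
`T = 0.5 * 0.9^iteration` (broad early exploration, local late
refinement), clipped to the bounds; parents are the top ~20% of the
population by (rank, summed cost, index); evaluation uses the same
instance seeds for every candidate (common random numbers); ties within a
front break by candidate index. An elitist archive keeps every feasible
non-dominated candidate seen, so the best summed cost is non-increasing —
this archive is the returned front. If an entire population is infeasible
the iteration restarts from a fresh log-uniform draw; after 5 consecutive
restarts the search raises an explicit error. Full scale is 50 iterations
× 600 candidates × 5 instances; all scales shrink for desk runs, and
`iterations=0` evaluates the initial population without proposing.

The "no selectivity constraint" condition is reproducible with two
independent toggles — dropping the selectivity objective from dominance
(`include_selectivity=False`) and/or disabling the inclusion criteria
(`check_inclusion=False`) — because the published description does not
disambiguate which was meant.

The package does **not** attempt to reproduce the published tuned weight
values themselves: the search is stochastic and its optima are plausibly
non-identifiable, so the catalog consumes those values as inputs instead.

## What the tests establish

Unit and property tests pin the battery combinatorics, the algebraic fixed
points of the dynamics, the metric definitions against an independent
brute-force oracle, the weight distributions (including a seeded KS test
against the exact uniform law), the catalog contents, and the optimizer's
bookkeeping (bounds, elitism, Pareto ranks vs. an O(n²) dominance oracle,
bit-identical determinism given the master seed). The acceptance suite
additionally verifies the qualitative architecture ordering: log-normal
beats uniform weights, indirect feedback inhibition beats direct, and
removing the recurrent excitatory feedback collapses the advantage.

These simulations probe exactly the stated world — binary combinatorial
inputs, rate units, fixed kinetics — so green tests say nothing about
temporal phenomena (oscillations, adaptation, facilitation), dendritic
nonlinearities, plasticity, or graded inputs, all of which are outside the
model class. Ordering checks at 5 instances are statements about the
seeded ensemble means, not about every individual realization.
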