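# dgcircuit

Rate-network simulation and pattern-separation analysis for dentate
gyrus-like circuit motifs.

## The scientific problem

The hippocampal dentate gyrus turns dense, overlapping cortical input
patterns into ultrasparse, nearly non-overlapping output patterns — the
"pattern separation" believed to underlie the storage of similar memories
as distinct traces. `dgcircuit` is a toolkit for asking which *circuit
architecture* features produce this transformation before any learning
occurs: it simulates small conductance-based threshold-linear rate networks
built from an excitatory output population (granule-cell-like), feedforward
and feedback inhibitory interneurons, and recurrently connected excitatory
feedback interneurons (mossy-cell-like), challenged with every combination
of a small set of binary afferent inputs.

It is intended for computational neuroscientists studying circuit motifs
for sparse coding, and as a reproducible reference implementation of the
published nine-variant dentate-circuit comparison it packages.

## Model

Every non-input unit is a single-compartment leaky integrator,

    tau_cell dV_i/dt = -V_i + I_i R,        I_i = sum_j w_ij g_ij (E_j - V_i),

with saturable conductance-based synapses whose normalized conductance
rises toward the presynaptic activity `a_j` and decays exponentially:

    dg_ij/dt = -g_ij / tau_decay + max(a_j - g_ij, 0) / tau_rise.

Unit activity is threshold-linear in voltage: 0 below +10 mV, rising to 1
at the excitatory reversal potential (+60 mV; inhibitory synapses reverse
at -10 mV). Input units are clamped to the bits of the presented pattern.
The input battery is the full combinatorial set of `2^7 = 128` binary
patterns over 7 input units; each pattern is presented for 350 ms and
steady activities are the time-average over the final 200 ms.

Output codes are scored with three metrics, all in [0, 1], larger better:

* **sparsity** of pattern *k*: `1 - F_units,k`, the complement of the
  fraction of units active for that pattern (0 if no unit is active);
* **selectivity** of unit *i*: `1 - F_patterns,i`, the complement of the
  fraction of patterns the unit responds to (0 if it never responds);
* **discriminability** of patterns *k, l*: `1 - C_kl`, the complement of
  the cosine similarity of the two population vectors (0 if either pattern
  silences the population).

Synaptic weights are sampled i.i.d. — uniform on `[0, 2*mean]` except for
excitatory→excitatory projections, which use a rescaled log-normal — and
the per-projection mean weights of the nine catalog variants were tuned by
a population-based multi-objective simulated-annealing search with
non-dominated sorting, which the `optimize` module reimplements.

## Worked example

```python
from dgcircuit import compare_experiments, simulate_experiment

direct = simulate_experiment("ff-direct-fb", instances=5, seed=1)
indirect = simulate_experiment("ff-indirect-fb", instances=5, seed=1)
ks = compare_experiments(indirect, direct, n_comparisons=6)
for metric in ("sparsity", "selectivity", "discriminability"):
    print(metric, round(direct.summary.mean_metric(metric), 4),
          round(indirect.summary.mean_metric(metric), 4),
          f"{ks[metric].adjusted_pvalue:.2e}")
```

prints

```
sparsity 0.5925 0.8377 1.07e-106
selectivity 0.5128 0.8409 1.59e-94
discriminability 0.4483 0.5012 3.82e-236
```

i.e. routing feedback inhibition *indirectly* through recurrently connected
excitatory feedback interneurons — instead of letting output units drive
feedback inhibition directly — raises mean output sparsity from 0.59 to
0.84, selectivity from 0.51 to 0.84 and pairwise discriminability from 0.45
to 0.50 across five independent weight realizations, with two-sample
Kolmogorov-Smirnov tests (Bonferroni-adjusted) rejecting equality of every
pooled distribution.

The `examples/` directory contains one short narrative script per
capability: building the battery, simulating a variant, tracing a single
presentation, comparing architectures, and running a desk-scale weight
search.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch: it generates the
combinatorial battery, scores the ideal one-hot reference, simulates three
catalog variants on five seeded weight instances each, reports their mean
metrics, and performs a small seeded optimization run, writing the results
JSON to `--out`.
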