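"""Build the combinatorial input battery and its ideal one-hot reference.

Seven binary input units yield 2^7 = 128 distinct patterns spanning every
possible combination of active inputs, from the empty pattern to all seven.
The ideal reference assigns each pattern its own dedicated output unit —
the most sparse, selective and discriminable code 128 output units can
produce.
"""

import numpy as np

from dgcircuit import (
    MetricsReport,
    generate_combinatorial_patterns,
    ideal_output,
)

battery = generate_combinatorial_patterns(7)
print(f"patterns: {battery.n_patterns}, bits per pattern: {battery.n_bits}")
print(f"active inputs per pattern: min {battery.patterns.sum(1).min()}, "
      f"max {battery.patterns.sum(1).max()}")
print(f"each input unit is active in {battery.patterns[:, 0].mean():.0%} of patterns")

ideal = MetricsReport.from_activity(ideal_output(battery, 128))
print(f"\nideal one-hot code: sparsity {ideal.sparsity.mean():.4f} "
      f"(= 1 - 1/128 = {1 - 1/128:.4f})")
print(f"ideal discriminability of distinct pairs: "
      f"{ideal.discriminability_pairs.mean():.1f}")
# every pattern activates exactly one output unit, and no two patterns
# share a unit, so the representation cannot be improved upon
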