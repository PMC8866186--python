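"""Combinatorial binary input batteries and the ideal one-hot reference.

The circuit is probed with every possible combination of a small number of
binary afferent inputs: with ``n_bits`` input units there are ``2**n_bits``
distinct patterns, including the all-zero pattern, and each input unit is
active in exactly half of them. Patterns are ordered canonically by the
integer value of their bit string (bit 0 = least significant), so pattern
``k`` is simply the binary expansion of ``k``. The battery therefore spans a
wide range of total input activity levels (0..n_bits active units) while
individual patterns remain highly overlapping.

``ideal_output`` builds the maximally sparse reference code — each pattern
represented by a single dedicated output unit — used only as a comparison
distribution for the pattern-separation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ActivityMatrix

_MAX_BITS = 20  # guard against combinatorial explosion


@dataclass(frozen=True)
class PatternSet:
    """The full combinatorial battery of binary input patterns.

    ``patterns`` has shape ``(2**n_bits, n_bits)``; row ``k`` is the binary
    expansion of ``k`` with bit 0 in column 0.
    """

    n_bits: int
    patterns: np.ndarray

    def __len__(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def as_activity(self) -> ActivityMatrix:
        """View the battery itself as an (input-population) activity matrix."""
        return ActivityMatrix(self.patterns.astype(float), population="Input")


def generate_combinatorial_patterns(n_bits: int) -> PatternSet:
    """Generate all ``2**n_bits`` binary input patterns in canonical order.

    Parameters
    ----------
    n_bits
        Number of binary input units; must satisfy ``1 <= n_bits <= 20``.

    Returns
    -------
    PatternSet
        All distinct binary vectors of length ``n_bits``, ordered by
        ascending integer value of the bit string.
    """
    if not isinstance(n_bits, (int, np.integer)) or isinstance(n_bits, bool):
        raise TypeError(f"n_bits must be an integer, got {type(n_bits).__name__}")
    if not 1 <= n_bits <= _MAX_BITS:
        raise ValueError(f"n_bits must be in [1, {_MAX_BITS}], got {n_bits}")
    codes = np.arange(2**n_bits, dtype=np.int64)
    bits = ((codes[:, None] >> np.arange(n_bits)) & 1).astype(np.uint8)
    return PatternSet(n_bits=int(n_bits), patterns=bits)


def ideal_output(pattern_set: PatternSet, n_output: int) -> ActivityMatrix:
    """One-hot reference output: pattern ``k`` activates output unit ``k`` only.

    This is the maximally sparse, selective and discriminable code an output
    population of ``n_output`` units could produce for the battery. Unit
    assignment follows pattern index (any permutation is metric-equivalent).

    Parameters
    ----------
    pattern_set
        The input battery to represent.
    n_output
        Output population size; must be at least ``len(pattern_set)``.
    """
    n_patterns = len(pattern_set)
    if n_output < n_patterns:
        raise ValueError(
            f"n_output ({n_output}) must be >= number of patterns ({n_patterns})"
        )
    out = np.zeros((n_patterns, n_output), dtype=float)
    out[np.arange(n_patterns), np.arange(n_patterns)] = 1.0
    return ActivityMatrix(out, population="Ideal")
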