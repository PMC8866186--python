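"""Shared in-memory containers for steady-state population activity.

The central exchange object is :class:`ActivityMatrix`: a patterns x units
array of time-averaged steady activities in [0, 1] for one cell population.
All downstream metrics treat "nonzero activity" as activity greater than
``ACTIVITY_EPS`` — the set-membership definitions of the sparsity /
selectivity / discriminability metrics are stated on exact zeros, which is
unsafe in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Activity above this value counts as "nonzero" for all metrics and
#: feasibility criteria (floating-point guard; shared across modules).
ACTIVITY_EPS = 1e-6


@dataclass
class ActivityMatrix:
    """Time-averaged steady activities for one population.

    Parameters
    ----------
    values
        Array of shape ``(n_patterns, n_units)`` with entries in [0, 1].
        Row ``k`` is the population response to input pattern ``k``.
    population
        Name of the cell population (e.g. ``"Output"``).
    seed
        Seed of the network instance that produced the activities, if any.
    """

    values: np.ndarray
    population: str = "Output"
    seed: int | None = None
    eps: float = field(default=ACTIVITY_EPS, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(
                f"activity matrix must be 2-D (patterns x units), "
                f"got shape {self.values.shape}"
            )

    @property
    def n_patterns(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of entries counted as nonzero activity."""
        return self.values > self.eps
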