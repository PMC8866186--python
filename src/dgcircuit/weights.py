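"""Synaptic weight sampling and the catalog of published circuit variants.

Weights for each projection between two populations are drawn i.i.d. from a
distribution parameterized only by its mean: a uniform distribution on
[0, 2*mean] for inhibitory synapses and excitatory synapses onto inhibitory
neurons, or a rescaled log-normal (exp of a standard normal, multiplicatively
rescaled so the realized sample mean equals the requested mean exactly) for
excitatory synapses onto excitatory neurons — the skewed distribution seen
experimentally, where most synapses are weak but a minority are much
stronger than average.

The catalog enumerates the nine tuned network configurations: excitatory-
only networks with uniform or log-normal input weights, feedforward
inhibition (with and without the unit-selectivity constraint during
tuning), feedback inhibition alone or combined with feedforward inhibition
(direct recruitment by output units), and the mossy-cell-like architectures
in which feedback inhibition is recruited indirectly through a recurrently
connected excitatory feedback population — with variants removing the
recurrence or adding the direct excitatory feedback connection onto the
output units.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .dynamics import NetworkInstance, PopulationSpec, SimulationSettings

__all__ = [
    "ProjectionSpec",
    "WeightMatrix",
    "VariantConfig",
    "WEIGHT_BOUNDS",
    "VARIANT_NAMES",
    "default_populations",
    "default_distribution",
    "sample_uniform_weights",
    "sample_lognormal_weights",
    "variant_catalog",
    "get_variant",
    "realize_instance",
]

#: Mean-weight bounds used during optimization (dimensionless).
WEIGHT_BOUNDS = (0.01, 1.0)

_EXCITATORY = {"Input", "Output", "FB_Exc"}
_INHIBITORY = {"FF_Inh", "FB_Inh"}

_E_EXC, _E_INH = 60.0, -10.0


def default_populations() -> dict[str, PopulationSpec]:
    """Standard cell parameters shared by every catalog variant.

    7 binary input units; 128 excitatory output units (granule-cell-like,
    tau_cell 50 ms); 7-unit feedforward and feedback inhibitory populations
    (tau_cell 20 ms, slower inhibitory synapses, E_rev -10 mV); 7 excitatory
    feedback units (mossy-cell-like, tau_cell 50 ms). Synaptic kinetics
    attach to the presynaptic population: tau_rise 1 ms everywhere,
    tau_decay 10 ms for excitatory and 20 ms for inhibitory sources.
    """
    return {
        "Input": PopulationSpec("Input", 7, None, 1e-3, 1e-2, _E_EXC, is_input=True),
        "Output": PopulationSpec("Output", 128, 0.05, 1e-3, 1e-2, _E_EXC),
        "FF_Inh": PopulationSpec("FF_Inh", 7, 0.02, 1e-3, 2e-2, _E_INH),
        "FB_Inh": PopulationSpec("FB_Inh", 7, 0.02, 1e-3, 2e-2, _E_INH),
        "FB_Exc": PopulationSpec("FB_Exc", 7, 0.05, 1e-3, 1e-2, _E_EXC),
    }


def default_distribution(pre: str, post: str) -> str:
    """Distribution rule: log-normal for excitatory->excitatory, else uniform."""
    return "log-normal" if pre in _EXCITATORY and post in _EXCITATORY else "uniform"


@dataclass(frozen=True)
class ProjectionSpec:
    """A directed all-to-all connection between two populations."""

    pre: str
    post: str
    distribution: str
    mean_weight: float
    allow_autapse: bool = False

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "log-normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        lo, hi = WEIGHT_BOUNDS
        if not lo <= self.mean_weight <= hi:
            raise ValueError(
                f"{self.pre}->{self.post}: mean weight {self.mean_weight} "
                f"outside bounds [{lo}, {hi}]"
            )


@dataclass
class WeightMatrix:
    """Realized per-synapse weights for one projection, shape (n_post, n_pre)."""

    pre: str
    post: str
    values: np.ndarray
    distribution: str = "uniform"
    mean_weight: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("weight matrix must be 2-D (n_post, n_pre)")
        if np.any(self.values < 0):
            raise ValueError("synaptic weights must be nonnegative")


@dataclass(frozen=True)
class VariantConfig:
    """A named circuit architecture: populations plus projection means."""

    name: str
    projections: tuple[ProjectionSpec, ...]

    def populations(self) -> dict[str, PopulationSpec]:
        """Populations used by this variant (Input/Output plus any referenced)."""
        all_pops = default_populations()
        used = {"Input", "Output"}
        for p in self.projections:
            used.update((p.pre, p.post))
        return {name: spec for name, spec in all_pops.items() if name in used}

    def projection(self, pre: str, post: str) -> ProjectionSpec:
        for p in self.projections:
            if p.pre == pre and p.post == post:
                return p
        raise KeyError(f"variant {self.name!r} has no projection {pre}->{post}")

    def with_mean_weights(self, means: dict[tuple[str, str], float]) -> "VariantConfig":
        """Copy of this variant with some projection means replaced."""
        new = []
        for p in self.projections:
            m = means.get((p.pre, p.post))
            new.append(p if m is None else replace(p, mean_weight=float(m)))
        return VariantConfig(self.name, tuple(new))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_uniform_weights(mean: float, shape, rng_seed=None) -> np.ndarray:
    """I.i.d. weights from U(0, 2*mean); the expected sample mean is ``mean``."""
    if mean <= 0:
        raise ValueError(f"mean weight must be > 0, got {mean}")
    return _rng(rng_seed).uniform(0.0, 2.0 * mean, size=shape)


def sample_lognormal_weights(mean: float, shape, rng_seed=None) -> np.ndarray:
    """Rescaled log-normal weights: exp(N(0,1)) scaled to the exact sample mean.

    All values are strictly positive and right-skewed (sample median below
    the sample mean); the whole draw is rescaled multiplicatively so the
    realized sample mean equals ``mean`` to machine precision.
    """
    if mean <= 0:
        raise ValueError(f"mean weight must be > 0, got {mean}")
    w = np.exp(_rng(rng_seed).standard_normal(size=shape))
    return w * (mean / w.mean())


# Tuned mean weights for the nine published configurations. A missing
# (pre, post) key means the projection is absent from that architecture.
_CATALOG: dict[str, dict[tuple[str, str], float]] = {
    "no-inh-uniform": {("Input", "Output"): 0.1135},
    "no-inh-lognormal": {("Input", "Output"): 0.0681},
    "ff-inh": {
        ("Input", "Output"): 0.1905,
        ("Input", "FF_Inh"): 0.1336,
        ("FF_Inh", "Output"): 0.9996,
    },
    "ff-inh-no-selectivity": {
        ("Input", "Output"): 0.1026,
        ("Input", "FF_Inh"): 0.2319,
        ("FF_Inh", "Output"): 0.7684,
    },
    "fb-inh": {
        ("Input", "Output"): 0.0702,
        ("Output", "FB_Inh"): 0.9963,
        ("FB_Inh", "Output"): 0.0100,
    },
    "ff-direct-fb": {
        ("Input", "Output"): 0.0775,
        ("Input", "FF_Inh"): 0.9183,
        ("FF_Inh", "Output"): 0.0125,
        ("Output", "FB_Inh"): 0.9920,
        ("FB_Inh", "Output"): 0.0100,
    },
    "ff-indirect-fb": {
        ("Input", "Output"): 0.3891,
        ("Input", "FF_Inh"): 0.1640,
        ("FF_Inh", "Output"): 0.3011,
        ("FB_Inh", "Output"): 0.9994,
        ("Output", "FB_Exc"): 0.0167,
        ("FB_Exc", "FB_Exc"): 0.7891,
        ("FB_Exc", "FB_Inh"): 0.8583,
    },
    "indirect-fb-no-recurrent": {
        ("Input", "Output"): 0.0763,
        ("Input", "FF_Inh"): 0.9754,
        ("FF_Inh", "Output"): 0.0109,
        ("FB_Inh", "Output"): 0.0111,
        ("Output", "FB_Exc"): 0.9216,
        ("FB_Exc", "FB_Inh"): 0.9366,
    },
    "indirect-fb-plus-output": {
        ("Input", "Output"): 0.2090,
        ("Input", "FF_Inh"): 0.4825,
        ("FF_Inh", "Output"): 0.0110,
        ("FB_Inh", "Output"): 0.9983,
        ("Output", "FB_Exc"): 0.0158,
        ("FB_Exc", "FB_Exc"): 0.9333,
        ("FB_Exc", "FB_Inh"): 0.7726,
        ("FB_Exc", "Output"): 0.0423,
    },
}

VARIANT_NAMES = tuple(_CATALOG)


def _build_variant(name: str) -> VariantConfig:
    projections = []
    for (pre, post), mean in _CATALOG[name].items():
        # the uniform-weights control deliberately overrides the
        # exc->exc => log-normal rule on its only projection
        dist = "uniform" if name == "no-inh-uniform" else default_distribution(pre, post)
        projections.append(ProjectionSpec(pre, post, dist, mean))
    return VariantConfig(name, tuple(projections))


def variant_catalog() -> list[VariantConfig]:
    """All nine tuned circuit configurations with their published mean weights."""
    return [_build_variant(name) for name in VARIANT_NAMES]


def get_variant(name: str) -> VariantConfig:
    """Look up a single catalog variant by name."""
    if name not in _CATALOG:
        raise KeyError(
            f"unknown variant {name!r}; available: {', '.join(VARIANT_NAMES)}"
        )
    return _build_variant(name)


def _projection_seed(instance_seed: int, pre: str, post: str) -> np.random.SeedSequence:
    # stable per-(instance, projection) sub-seed: adding or removing other
    # projections never perturbs this projection's draw
    tag = zlib.crc32(f"{pre}->{post}".encode())
    return np.random.SeedSequence(entropy=int(instance_seed), spawn_key=(tag,))


def realize_instance(
    variant: VariantConfig,
    instance_seed: int,
    settings: SimulationSettings | None = None,
) -> NetworkInstance:
    """Sample all projection weight matrices for one network instance.

    Each projection uses a deterministic sub-seed derived from
    ``instance_seed`` and the projection's (pre, post) names. Recurrent
    projections have their diagonal (autapses) zeroed unless
    ``allow_autapse`` is set; the remaining entries are rescaled so the mean
    over actual synapses equals the requested mean.
    """
    populations = variant.populations()
    matrices = []
    for proj in variant.projections:
        n_post = populations[proj.post].size
        n_pre = populations[proj.pre].size
        rng = np.random.default_rng(_projection_seed(instance_seed, proj.pre, proj.post))
        sampler = (
            sample_lognormal_weights
            if proj.distribution == "log-normal"
            else sample_uniform_weights
        )
        values = sampler(proj.mean_weight, (n_post, n_pre), rng)
        if proj.pre == proj.post and not proj.allow_autapse:
            np.fill_diagonal(values, 0.0)
            off = values[~np.eye(n_post, dtype=bool)]
            if off.mean() > 0:
                values *= proj.mean_weight / off.mean()
        matrices.append(
            WeightMatrix(
                pre=proj.pre,
                post=proj.post,
                values=values,
                distribution=proj.distribution,
                mean_weight=proj.mean_weight,
            )
        )
    return NetworkInstance(
        populations=populations,
        projections=matrices,
        settings=settings or SimulationSettings(),
        instance_seed=int(instance_seed),
    )
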