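"""Conductance-based threshold-linear rate-network dynamics.

Each non-input unit is a single-compartment leaky integrator,

    tau_cell * dV_i/dt = -V_i + I_i * R,

driven by saturable conductance-based synapses,

    I_i = sum_j w_ij * g_ij * (E_j - V_i),

where the normalized conductance g rises toward the presynaptic activity
with time constant tau_rise and decays with tau_decay:

    dg/dt = -g / tau_decay + max(a_pre - g, 0) / tau_rise.

Unit activity is a piecewise-linear function of voltage: zero below the
activation threshold (+10 mV), rising linearly to one at the excitatory
reversal potential (+60 mV). Input units carry no intrinsic dynamics; their
activities are clamped to the bits of the presented binary pattern for the
whole simulation. Synaptic kinetics and reversal potential attach to the
*presynaptic* population, so a conductance state depends only on its source
unit: one state variable per presynaptic unit is integrated and shared
exactly across all of that unit's targets.

The battery runner integrates all patterns of a :class:`~dgcircuit.patterns.
PatternSet` as a single block-diagonal ODE system (patterns never interact,
so the dynamics stay exactly independent; only the adaptive step sequence is
shared), then averages each unit's activity over the final
``average_window`` seconds to obtain steady activities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .containers import ActivityMatrix
from .patterns import PatternSet

if TYPE_CHECKING:  # pragma: no cover
    from .weights import WeightMatrix

__all__ = [
    "PopulationSpec",
    "SimulationSettings",
    "NetworkInstance",
    "SimulationResult",
    "IntegrationError",
    "activation",
    "synaptic_current",
    "conductance_derivative",
    "simulate_pattern",
    "run_battery",
]


class IntegrationError(RuntimeError):
    """Raised when the IVP solver fails or produces non-finite state."""


@dataclass(frozen=True)
class PopulationSpec:
    """A named cell population and the kinetics of the synapses it makes.

    ``tau_cell`` is the membrane time constant in seconds (``None`` for the
    clamped input population). ``syn_tau_rise`` / ``syn_tau_decay`` / and
    ``syn_E_rev`` describe synapses *made by* this population: all of a
    unit's outgoing synapses share kinetics and reversal potential.
    """

    name: str
    size: int
    tau_cell: float | None
    syn_tau_rise: float
    syn_tau_decay: float
    syn_E_rev: float
    is_input: bool = False

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"population {self.name!r}: size must be >= 1")
        if self.syn_tau_rise <= 0 or self.syn_tau_decay <= 0:
            raise ValueError(
                f"population {self.name!r}: synaptic time constants must be > 0"
            )
        if self.is_input:
            if self.tau_cell is not None:
                raise ValueError(
                    f"input population {self.name!r} has no membrane dynamics; "
                    "tau_cell must be None"
                )
        elif self.tau_cell is None or self.tau_cell <= 0:
            raise ValueError(f"population {self.name!r}: tau_cell must be > 0")


@dataclass(frozen=True)
class SimulationSettings:
    """Protocol and solver settings for one pattern presentation.

    Defaults follow the standard protocol: 350 ms presentations, steady
    activities averaged over the final 200 ms, resting voltage 0 mV,
    activation threshold +10 mV, activity saturating at +60 mV. The input
    resistance ``R`` is dimensionless and folded into the weight scale
    (R = 1).
    """

    duration: float = 0.35
    average_window: float = 0.2
    v_rest: float = 0.0
    v_threshold: float = 10.0
    v_max: float = 60.0
    input_resistance: float = 1.0
    rtol: float = 1e-6
    atol: float = 1e-8
    record_dt: float = 1e-3
    method: str = "RK45"

    def __post_init__(self) -> None:
        if not 0 < self.average_window < self.duration:
            raise ValueError("require 0 < average_window < duration")
        if not self.v_rest < self.v_threshold < self.v_max:
            raise ValueError("require v_rest < v_threshold < v_max")
        if self.record_dt <= 0:
            raise ValueError("record_dt must be > 0")


def activation(v: np.ndarray | float, settings: SimulationSettings) -> np.ndarray | float:
    """Piecewise-linear activation: 0 below threshold, 1 at ``v_max``."""
    scale = settings.v_max - settings.v_threshold
    return np.clip((np.asarray(v, dtype=float) - settings.v_threshold) / scale, 0.0, 1.0)


def synaptic_current(
    weights: np.ndarray | float,
    conductances: np.ndarray | float,
    E: float,
    v: np.ndarray | float,
) -> np.ndarray | float:
    """Current from one source population: ``sum_j w_ij g_j (E - v_i)``.

    With 2-D ``weights`` of shape ``(n_post, n_pre)`` and 1-D conductances,
    returns the per-target current vector. With matching scalar/1-D inputs,
    returns the summed current onto a single target at voltage ``v``.
    """
    w = np.asarray(weights, dtype=float)
    g = np.asarray(conductances, dtype=float)
    if w.ndim == 2:
        if g.shape[0] != w.shape[1]:
            raise ValueError(
                f"conductance length {g.shape} does not match weight matrix {w.shape}"
            )
        return (E - np.asarray(v, dtype=float)) * (w @ g)
    if w.shape != g.shape:
        raise ValueError(f"weight shape {w.shape} != conductance shape {g.shape}")
    return (E - v) * np.sum(w * g)


def conductance_derivative(
    g: np.ndarray | float,
    a_pre: np.ndarray | float,
    tau_rise: float,
    tau_decay: float,
) -> np.ndarray | float:
    """dg/dt for a saturable conductance driven by presynaptic activity."""
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("synaptic time constants must be > 0")
    g = np.asarray(g, dtype=float)
    a = np.asarray(a_pre, dtype=float)
    return -g / tau_decay + np.maximum(a - g, 0.0) / tau_rise


@dataclass
class NetworkInstance:
    """One realized network: populations, sampled weights, protocol settings."""

    populations: Mapping[str, PopulationSpec]
    projections: Sequence["WeightMatrix"]
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    instance_seed: int | None = None

    def __post_init__(self) -> None:
        self.populations = dict(self.populations)
        self.projections = tuple(self.projections)
        for proj in self.projections:
            if proj.pre not in self.populations or proj.post not in self.populations:
                raise ValueError(
                    f"projection {proj.pre}->{proj.post} references unknown population"
                )
            pre = self.populations[proj.pre]
            post = self.populations[proj.post]
            if proj.values.shape != (post.size, pre.size):
                raise ValueError(
                    f"projection {proj.pre}->{proj.post}: weight shape "
                    f"{proj.values.shape} != (post.size, pre.size) = "
                    f"({post.size}, {pre.size})"
                )
            if post.is_input:
                raise ValueError(
                    f"projection {proj.pre}->{proj.post}: input units receive "
                    "no synapses"
                )

    @property
    def input_population(self) -> PopulationSpec:
        inputs = [p for p in self.populations.values() if p.is_input]
        if len(inputs) != 1:
            raise ValueError("network must contain exactly one input population")
        return inputs[0]


@dataclass
class SimulationResult:
    """Full traces and steady activities for one presented pattern."""

    t: np.ndarray
    voltages: dict[str, np.ndarray]  # pop -> (n_t, size), non-input pops
    conductances: dict[str, np.ndarray]  # source pop -> (n_t, size)
    activities: dict[str, np.ndarray]  # pop -> (n_t, size), all pops
    steady_activity: dict[str, np.ndarray]  # pop -> (size,)


class _CompiledNetwork:
    """State layout and vectorized right-hand side for one instance."""

    def __init__(self, instance: NetworkInstance):
        self.instance = instance
        pops = instance.populations
        self.input_pop = instance.input_population
        self.dyn_pops = [p for p in pops.values() if not p.is_input]
        source_names = {proj.pre for proj in instance.projections}
        # fixed layout: voltage blocks (dynamic pops), then conductance
        # blocks (one state per presynaptic unit of each source population)
        self.src_pops = [p for p in pops.values() if p.name in source_names]
        self.v_slices: dict[str, slice] = {}
        self.g_slices: dict[str, slice] = {}
        offset = 0
        for p in self.dyn_pops:
            self.v_slices[p.name] = slice(offset, offset + p.size)
            offset += p.size
        for p in self.src_pops:
            self.g_slices[p.name] = slice(offset, offset + p.size)
            offset += p.size
        self.n_v = sum(p.size for p in self.dyn_pops)
        self.n_g = offset - self.n_v
        self.n_state = offset
        # incoming projections per dynamic population
        self.incoming: dict[str, list] = {p.name: [] for p in self.dyn_pops}
        for proj in instance.projections:
            pre = pops[proj.pre]
            self.incoming[proj.post].append((proj.values, proj.pre, pre.syn_E_rev))
        self._assemble_global()

    def _assemble_global(self) -> None:
        """Flatten the per-projection structure into global arrays.

        With g indexed over all source units and V over all dynamic units,
        the synaptic current is I = A g - V * (B g) where B stacks the raw
        weight matrices and A weighs each column block by its source
        population's reversal potential. Conductance kinetics become two
        global time-constant vectors plus a gather of presynaptic
        activities.
        """
        n_v, n_g = self.n_v, self.n_g
        R = self.instance.settings.input_resistance
        g_off = {name: sl.start - n_v for name, sl in self.g_slices.items()}
        self.B = np.zeros((n_v, n_g))
        self.A = np.zeros((n_v, n_g))
        for proj in self.instance.projections:
            E = self.instance.populations[proj.pre].syn_E_rev
            rows = self.v_slices[proj.post]
            cols = slice(
                g_off[proj.pre], g_off[proj.pre] + proj.values.shape[1]
            )
            self.B[rows, cols] += proj.values
            self.A[rows, cols] += E * proj.values
        # single stacked matmul per RHS call: rows [0, n_v) give B g (the
        # total conductance drive), rows [n_v, 2 n_v) give A g (the
        # reversal-weighted drive); R is folded in here
        self.stacked = np.vstack([R * self.B, R * self.A])
        self.inv_tau_r = np.empty(n_g)
        self.inv_tau_d = np.empty(n_g)
        self.inv_tau_cell = np.empty(n_v)
        for p in self.src_pops:
            sl = slice(g_off[p.name], g_off[p.name] + p.size)
            self.inv_tau_r[sl] = 1.0 / p.syn_tau_rise
            self.inv_tau_d[sl] = 1.0 / p.syn_tau_decay
        for p in self.dyn_pops:
            self.inv_tau_cell[self.v_slices[p.name]] = 1.0 / p.tau_cell
        # which g rows are fed by dynamic units (vs clamped inputs), and the
        # V row each of those source units corresponds to
        dyn_g_rows, v_src_idx = [], []
        in_g_rows, in_src_idx = [], []
        for p in self.src_pops:
            for j in range(p.size):
                g_row = g_off[p.name] + j
                if p.is_input:
                    in_g_rows.append(g_row)
                    in_src_idx.append(j)
                else:
                    dyn_g_rows.append(g_row)
                    v_src_idx.append(self.v_slices[p.name].start + j)
        self.dyn_g_rows = np.array(dyn_g_rows, dtype=int)
        self.v_src_idx = np.array(v_src_idx, dtype=int)
        self.in_g_rows = np.array(in_g_rows, dtype=int)
        self.in_src_idx = np.array(in_src_idx, dtype=int)

    def rhs(self, clamped_input: np.ndarray, accumulate: bool = False):
        """Return f(t, y) for a batch; ``clamped_input`` is (n_in, n_batch).

        With ``accumulate=True`` the state carries ``n_v`` extra rows whose
        derivative is the instantaneous activity of each dynamic unit, so
        their increase over the averaging window is the exact time integral
        of activity.
        """
        s = self.instance.settings
        inv_scale = 1.0 / (s.v_max - s.v_threshold)
        thr = s.v_threshold
        n_v, n_g = self.n_v, self.n_g
        n_state = self.n_state + (n_v if accumulate else 0)
        n_batch = clamped_input.shape[1]
        stacked = self.stacked
        inv_tau_r = self.inv_tau_r[:, None]
        inv_tau_d = self.inv_tau_d[:, None]
        inv_tau_cell = self.inv_tau_cell[:, None]
        # presynaptic activities: clamped input rows are constant, rows fed
        # by dynamic units are refreshed from V on every call
        a_pre = np.zeros((n_g, n_batch))
        if self.in_g_rows.size:
            a_pre[self.in_g_rows] = clamped_input[self.in_src_idx]
        dyn_g_rows, v_src_idx = self.dyn_g_rows, self.v_src_idx
        # scratch buffers (f is called sequentially by the solver; the
        # returned dy is always freshly allocated because the solver keeps
        # references to stage derivatives)
        sg = np.empty((2 * n_v, n_batch))
        tmp_g = np.empty((n_g, n_batch))

        def f(t: float, y: np.ndarray) -> np.ndarray:
            y = y.reshape(n_state, n_batch)
            V, g = y[:n_v], y[n_v : n_v + n_g]
            dy = np.empty_like(y)
            if accumulate:
                act = np.clip((V - thr) * inv_scale, 0.0, 1.0, out=dy[n_v + n_g :])
                if dyn_g_rows.size:
                    a_pre[dyn_g_rows] = act[v_src_idx]
            elif dyn_g_rows.size:
                a_pre[dyn_g_rows] = np.clip(
                    (V[v_src_idx] - thr) * inv_scale, 0.0, 1.0
                )
            np.matmul(stacked, g, out=sg)
            drive, current = sg[:n_v], sg[n_v:]
            drive *= V
            current -= drive
            current -= V
            np.multiply(current, inv_tau_cell, out=dy[:n_v])
            np.subtract(a_pre, g, out=tmp_g)
            np.maximum(tmp_g, 0.0, out=tmp_g)
            np.multiply(tmp_g, inv_tau_r, out=tmp_g)
            gd = dy[n_v : n_v + n_g]
            np.multiply(g, inv_tau_d, out=gd)
            np.subtract(tmp_g, gd, out=gd)
            return dy.reshape(-1)

        return f

    def _initial_state(self, n_batch: int, n_extra: int = 0) -> np.ndarray:
        s = self.instance.settings
        y0 = np.zeros((self.n_state + n_extra, n_batch))
        if s.v_rest != 0.0:
            y0[: self.n_v] = s.v_rest
        return y0

    def _check(self, sol, n_batch: int) -> None:
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                f"IVP solver failed (instance seed "
                f"{self.instance.instance_seed!r}, {n_batch} pattern(s)): "
                f"{sol.message}"
            )

    def _validate_bits(self, pattern_bits: np.ndarray) -> np.ndarray:
        bits = np.atleast_2d(np.asarray(pattern_bits, dtype=float))
        if bits.shape[1] != self.input_pop.size:
            raise ValueError(
                f"pattern length {bits.shape[1]} != input population size "
                f"{self.input_pop.size}"
            )
        return bits

    def steady_batch(self, pattern_bits: np.ndarray) -> np.ndarray:
        """Steady activities of all dynamic units, shape (n_v, n_batch).

        The steady value is the exact time average of activity over the
        final ``average_window``: the trajectory is integrated to the start
        of the window, then accumulator states dA/dt = activity are carried
        through the window and divided by its length.
        """
        s = self.instance.settings
        bits = self._validate_bits(pattern_bits)
        n_batch = bits.shape[0]
        t0 = s.duration - s.average_window
        y0 = self._initial_state(n_batch)
        sol1 = solve_ivp(
            self.rhs(bits.T),
            (0.0, t0),
            y0.reshape(-1),
            method=s.method,
            rtol=s.rtol,
            atol=s.atol,
        )
        self._check(sol1, n_batch)
        y1 = sol1.y[:, -1].reshape(self.n_state, n_batch)
        y2 = np.concatenate([y1, np.zeros((self.n_v, n_batch))])
        sol2 = solve_ivp(
            self.rhs(bits.T, accumulate=True),
            (t0, s.duration),
            y2.reshape(-1),
            method=s.method,
            rtol=s.rtol,
            atol=s.atol,
        )
        self._check(sol2, n_batch)
        acc = sol2.y[:, -1].reshape(self.n_state + self.n_v, n_batch)[self.n_state :]
        return np.clip(acc / s.average_window, 0.0, 1.0)

    def integrate(self, pattern_bits: np.ndarray, t_eval: np.ndarray) -> np.ndarray:
        """Integrate a batch of patterns; returns state (n_state, n_t, n_batch)."""
        s = self.instance.settings
        bits = self._validate_bits(pattern_bits)
        n_batch = bits.shape[0]
        sol = solve_ivp(
            self.rhs(bits.T),
            (0.0, s.duration),
            self._initial_state(n_batch).reshape(-1),
            method=s.method,
            t_eval=t_eval,
            rtol=s.rtol,
            atol=s.atol,
        )
        self._check(sol, n_batch)
        return sol.y.reshape(self.n_state, n_batch, -1).transpose(0, 2, 1)

    def window_t_eval(self) -> np.ndarray:
        s = self.instance.settings
        n = int(round(s.average_window / s.record_dt))
        return np.linspace(s.duration - s.average_window, s.duration, n + 1)

    def full_t_eval(self) -> np.ndarray:
        s = self.instance.settings
        n = int(round(s.duration / s.record_dt))
        return np.linspace(0.0, s.duration, n + 1)


def simulate_pattern(instance: NetworkInstance, pattern: np.ndarray) -> SimulationResult:
    """Present one binary pattern and return full traces + steady activities.

    The input population's activities are clamped to the pattern bits for
    the entire ``duration``; every other state starts from rest (``v_rest``,
    zero conductance). Steady activity is the time average over the final
    ``average_window`` seconds.
    """
    pattern = np.asarray(pattern, dtype=float).ravel()
    net = _CompiledNetwork(instance)
    s = instance.settings
    t = net.full_t_eval()
    state = net.integrate(pattern, t)[:, :, 0]  # (n_state, n_t)
    voltages, conductances, activities = {}, {}, {}
    for p in net.dyn_pops:
        V = state[net.v_slices[p.name]].T  # (n_t, size)
        voltages[p.name] = V
        activities[p.name] = np.asarray(activation(V, s))
    for p in net.src_pops:
        conductances[p.name] = state[net.g_slices[p.name]].T
    activities[net.input_pop.name] = np.broadcast_to(
        pattern, (t.size, pattern.size)
    ).copy()
    steady_v = net.steady_batch(pattern)[:, 0]
    steady = {net.input_pop.name: pattern.copy()}
    for p in net.dyn_pops:
        steady[p.name] = steady_v[net.v_slices[p.name]]
    return SimulationResult(
        t=t,
        voltages=voltages,
        conductances=conductances,
        activities=activities,
        steady_activity=steady,
    )


def run_battery(
    instance: NetworkInstance, pattern_set: PatternSet
) -> dict[str, ActivityMatrix]:
    """Present every pattern in the battery; return steady activities per population.

    Patterns are presented independently (state reset between patterns); the
    input population's matrix equals the pattern matrix itself since input
    units are clamped. Rows are ordered by pattern index.
    """
    net = _CompiledNetwork(instance)
    s = instance.settings
    if pattern_set.n_bits != net.input_pop.size:
        raise ValueError(
            f"pattern width {pattern_set.n_bits} != input population size "
            f"{net.input_pop.size}"
        )
    steady = net.steady_batch(pattern_set.patterns)  # (n_v, n_patterns)
    out: dict[str, ActivityMatrix] = {
        net.input_pop.name: ActivityMatrix(
            pattern_set.patterns.astype(float),
            population=net.input_pop.name,
            seed=instance.instance_seed,
        )
    }
    for p in net.dyn_pops:
        out[p.name] = ActivityMatrix(
            steady[net.v_slices[p.name]].T,
            population=p.name,
            seed=instance.instance_seed,
        )
    return out
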