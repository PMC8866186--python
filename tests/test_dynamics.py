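"""Membrane / conductance dynamics, fixed points and battery runs."""

import dataclasses

import numpy as np
import pytest

from dgcircuit import (
    NetworkInstance,
    PopulationSpec,
    SimulationSettings,
    WeightMatrix,
    activation,
    conductance_derivative,
    generate_combinatorial_patterns,
    get_variant,
    realize_instance,
    run_battery,
    simulate_pattern,
    synaptic_current,
)

E_EXC = 60.0


def single_synapse_network(w=0.5, settings=None, n_inputs=1):
    """Minimal chain: clamped input unit(s) -> one excitatory output unit."""
    pops = {
        "Input": PopulationSpec("Input", n_inputs, None, 1e-3, 1e-2, E_EXC, is_input=True),
        "Output": PopulationSpec("Output", 1, 0.05, 1e-3, 1e-2, E_EXC),
    }
    proj = WeightMatrix("Input", "Output", np.full((1, n_inputs), w))
    return NetworkInstance(pops, [proj], settings=settings or SimulationSettings())


class TestActivation:
    @pytest.mark.parametrize(
        "v,expected",
        [(10.0, 0.0), (60.0, 1.0), (35.0, 0.5), (-5.0, 0.0), (80.0, 1.0)],
    )
    def test_piecewise_linear_values(self, v, expected):
        assert activation(v, SimulationSettings()) == pytest.approx(expected)

    def test_vectorized(self):
        out = activation(np.array([0.0, 10.0, 35.0, 60.0]), SimulationSettings())
        assert np.allclose(out, [0.0, 0.0, 0.5, 1.0])


class TestSynapticCurrent:
    def test_hand_evaluated_example(self):
        # w g (E - v) = 0.5 * (10/11) * 60
        assert synaptic_current(0.5, 10 / 11, 60.0, 0.0) == pytest.approx(
            27.273, abs=1e-3
        )

    def test_zero_driving_force(self):
        assert synaptic_current(0.7, 0.9, 60.0, 60.0) == 0.0

    def test_zero_weights(self):
        assert synaptic_current(np.zeros(5), np.ones(5), 60.0, 12.0) == 0.0

    def test_matrix_form_matches_per_target_sum(self, rng):
        W = rng.uniform(0, 1, size=(3, 4))
        g = rng.uniform(0, 1, size=4)
        v = rng.uniform(0, 40, size=3)
        out = synaptic_current(W, g, E_EXC, v)
        expected = [(E_EXC - v[i]) * np.dot(W[i], g) for i in range(3)]
        assert np.allclose(out, expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            synaptic_current(np.ones((3, 4)), np.ones(5), 60.0, np.zeros(3))


class TestConductanceKinetics:
    def test_fixed_point_under_constant_drive(self):
        # dg/dt = 0 at g* = tau_decay / (tau_rise + tau_decay)
        gstar = 0.01 / (0.001 + 0.01)
        assert conductance_derivative(gstar, 1.0, 0.001, 0.01) == pytest.approx(
            0.0, abs=1e-12
        )
        assert conductance_derivative(gstar - 0.01, 1.0, 0.001, 0.01) > 0
        assert conductance_derivative(gstar + 0.01, 1.0, 0.001, 0.01) < 0

    def test_rest_is_a_fixed_point(self):
        assert conductance_derivative(0.0, 0.0, 0.001, 0.01) == 0.0

    def test_closed_form_decay(self):
        # with no presynaptic activity, g(t) = g0 exp(-t/tau_decay):
        # integrate dg/dt with explicit Euler at tiny dt and compare
        tau_d, g0, dt = 0.01, 0.8, 1e-6
        g = g0
        for _ in range(int(0.02 / dt)):
            g += dt * conductance_derivative(g, 0.0, 0.001, tau_d)
        assert g == pytest.approx(g0 * np.exp(-0.02 / tau_d), rel=1e-3)

    @pytest.mark.parametrize("tau_rise,tau_decay", [(0, 0.01), (0.001, -1)])
    def test_nonpositive_time_constants_rejected(self, tau_rise, tau_decay):
        with pytest.raises(ValueError):
            conductance_derivative(0.1, 0.5, tau_rise, tau_decay)


class TestSimulatePattern:
    def test_single_synapse_fixed_point(self):
        # algebraic fixed point of the coupled system with constant drive:
        # g* = tau_d/(tau_r+tau_d), V* = w g* E / (1 + w g*)
        long = SimulationSettings(duration=1.0, average_window=0.2)
        res = simulate_pattern(single_synapse_network(w=0.5, settings=long), [1])
        gstar = 0.01 / 0.011
        vstar = 0.5 * gstar * 60.0 / (1 + 0.5 * gstar)
        astar = (vstar - 10.0) / 50.0
        assert res.conductances["Input"][-1, 0] == pytest.approx(gstar, abs=1e-4)
        assert res.voltages["Output"][-1, 0] == pytest.approx(vstar, abs=1e-3)
        assert res.steady_activity["Output"][0] == pytest.approx(astar, abs=1e-4)

    def test_all_zero_pattern_is_silent(self, battery7):
        inst = realize_instance(get_variant("ff-indirect-fb"), 7)
        res = simulate_pattern(inst, np.zeros(7))
        for name, steady in res.steady_activity.items():
            assert np.all(steady == 0), f"{name} active with no input"
        for v in res.voltages.values():
            assert np.all(np.abs(v) < 1e-9)

    def test_doubling_duration_barely_changes_steady_state(self):
        res1 = simulate_pattern(single_synapse_network(), [1])
        longer = SimulationSettings(duration=0.7, average_window=0.2)
        res2 = simulate_pattern(single_synapse_network(settings=longer), [1])
        diff = abs(
            res1.steady_activity["Output"][0] - res2.steady_activity["Output"][0]
        )
        assert diff < 1e-3

    def test_bounded_state(self, battery7):
        inst = realize_instance(get_variant("ff-indirect-fb"), 2)
        res = simulate_pattern(inst, battery7.patterns[100])
        for v in res.voltages.values():
            assert v.min() >= -10.0 - 1e-6 and v.max() <= 60.0 + 1e-6
        for g in res.conductances.values():
            # tiny interpolation overshoot below zero is tolerated
            assert g.min() >= -1e-4 and g.max() <= 1.0 + 1e-4
        for a in res.activities.values():
            assert a.min() >= 0.0 and a.max() <= 1.0

    def test_wrong_pattern_length_rejected(self):
        with pytest.raises(ValueError):
            simulate_pattern(single_synapse_network(n_inputs=3), [1, 0])


class TestRunBattery:
    def test_input_activity_equals_pattern_matrix(self, battery7):
        inst = realize_instance(get_variant("no-inh-lognormal"), 1)
        acts = run_battery(inst, battery7)
        assert np.array_equal(acts["Input"].values, battery7.patterns)

    def test_rows_ordered_by_pattern_index(self, battery7):
        # battery row k must match an isolated presentation of pattern k
        inst = realize_instance(get_variant("no-inh-lognormal"), 1)
        acts = run_battery(inst, battery7)
        for k in (0, 37, 127):
            res = simulate_pattern(inst, battery7.patterns[k])
            assert np.allclose(
                acts["Output"].values[k], res.steady_activity["Output"], atol=1e-6
            )

    def test_excitatory_monotonicity_over_subset_pairs(self):
        """With only positive (uniform) input weights, a pattern whose active
        set contains another's cannot produce less total output drive."""
        battery5 = generate_combinatorial_patterns(5)
        pops = {
            "Input": PopulationSpec("Input", 5, None, 1e-3, 1e-2, E_EXC, is_input=True),
            "Output": PopulationSpec("Output", 16, 0.05, 1e-3, 1e-2, E_EXC),
        }
        rng = np.random.default_rng(11)
        proj = WeightMatrix("Input", "Output", rng.uniform(0, 0.3, size=(16, 5)))
        inst = NetworkInstance(pops, [proj])
        acts = run_battery(inst, battery5)
        totals = acts["Output"].values.sum(axis=1)
        bits = battery5.patterns.astype(bool)
        for k in range(32):
            for l in range(32):
                if k != l and np.all(bits[l] <= bits[k]):
                    assert totals[k] >= totals[l] - 1e-9

    def test_determinism(self, battery7):
        inst_a = realize_instance(get_variant("ff-inh"), 5)
        inst_b = realize_instance(get_variant("ff-inh"), 5)
        acts_a = run_battery(inst_a, battery7)
        acts_b = run_battery(inst_b, battery7)
        for name in acts_a:
            assert np.array_equal(acts_a[name].values, acts_b[name].values)

    def test_halved_solver_tolerances_do_not_move_steady_state(self, battery7):
        inst1 = realize_instance(get_variant("ff-inh"), 3)
        tight = dataclasses.replace(SimulationSettings(), rtol=5e-7, atol=5e-9)
        inst2 = realize_instance(get_variant("ff-inh"), 3, settings=tight)
        acts1 = run_battery(inst1, battery7)
        acts2 = run_battery(inst2, battery7)
        diff = np.abs(acts1["Output"].values - acts2["Output"].values).max()
        assert diff < 1e-4

    def test_activities_within_unit_interval(self, battery7):
        inst = realize_instance(get_variant("fb-inh"), 4)
        acts = run_battery(inst, battery7)
        for act in acts.values():
            assert act.values.min() >= 0.0 and act.values.max() <= 1.0


class TestSpecValidation:
    def test_population_validation(self):
        with pytest.raises(ValueError):
            PopulationSpec("Output", 0, 0.05, 1e-3, 1e-2, 60.0)
        with pytest.raises(ValueError):
            PopulationSpec("Output", 5, -0.05, 1e-3, 1e-2, 60.0)
        with pytest.raises(ValueError):
            PopulationSpec("Input", 5, 0.05, 1e-3, 1e-2, 60.0, is_input=True)

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SimulationSettings(duration=0.1, average_window=0.2)
        with pytest.raises(ValueError):
            SimulationSettings(v_threshold=-20.0)

    def test_projection_shape_validation(self):
        pops = {
            "Input": PopulationSpec("Input", 3, None, 1e-3, 1e-2, E_EXC, is_input=True),
            "Output": PopulationSpec("Output", 2, 0.05, 1e-3, 1e-2, E_EXC),
        }
        bad = WeightMatrix("Input", "Output", np.ones((3, 2)))
        with pytest.raises(ValueError):
            NetworkInstance(pops, [bad])
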