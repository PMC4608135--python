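"""Gate kinetics: steady-state curves, Q10 rescaling, fast/slow classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voltmem as vm
from voltmem.kinetics import V_SCAN_RANGE


@pytest.fixture
def nav_gate(nav16):
    return nav16.gates[0]


class TestSteadyState:
    def test_half_activation_gives_half_open(self, nav_gate):
        assert vm.evaluate_steady_state(nav_gate, -17.0) == pytest.approx(0.5)

    def test_saturates_at_depolarized_limit(self, nav_gate):
        assert abs(float(vm.evaluate_steady_state(nav_gate, 150.0)) - 1.0) < 1e-11

    def test_matches_boltzmann_formula(self, nav_gate):
        # direct scalar evaluation of the printed sigmoid at V = 48 mV
        expected = 1.0 / (1.0 + math.exp(-0.1565 * 65.0))
        assert float(vm.evaluate_steady_state(nav_gate, 48.0)) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.99996, abs=5e-6)

    @given(
        v_half=st.floats(-100, 50),
        slope=st.floats(0.01, 1.0),
        v=st.floats(-200, 200),
    )
    @settings(deadline=None, derandomize=True)
    def test_bounded_on_physiological_grid(self, v_half, slope, v):
        gate = vm.GateSpec(
            name="m", role="activation",
            steady_state_form=vm.SigmoidSteadyState(v_half, slope),
            timescale_form=vm.ConstantTimescale(1.0),
        )
        x = float(gate.steady_state(v))
        assert 0.0 <= x <= 1.0

    def test_monotone_increasing_for_activation(self, nav_gate):
        grid = np.linspace(*V_SCAN_RANGE, 801)
        vals = np.asarray(nav_gate.steady_state(grid))
        assert np.all(np.diff(vals) >= 0)  # saturates to float 0/1 at extremes
        window = grid[(grid > -60) & (grid < 20)]
        assert np.all(np.diff(np.asarray(nav_gate.steady_state(window))) > 0)
        assert np.all((vals >= 0) & (vals <= 1))


class TestQ10Rescaling:
    @pytest.mark.parametrize(
        "tau, t_exp, t_target, expected",
        [
            (9.0, 13.0, 23.0, 3.0),  # one decade warmer divides tau by Q10
            (5.0, 16.0, 16.0, 5.0),  # identity at equal temperatures
            (5.0, 16.0, 36.0, 5.0 / 9.0),  # two decades
        ],
    )
    def test_examples(self, tau, t_exp, t_target, expected):
        assert vm.rescale_timescale_q10(tau, t_exp, t_target) == pytest.approx(expected)

    @given(tau=st.floats(0.01, 1000), t_exp=st.floats(0, 40), t_target=st.floats(0, 40))
    @settings(deadline=None, derandomize=True)
    def test_round_trip_identity(self, tau, t_exp, t_target):
        there = vm.rescale_timescale_q10(tau, t_exp, t_target)
        back = vm.rescale_timescale_q10(there, t_target, t_exp)
        assert back == pytest.approx(tau, rel=1e-12)

    @pytest.mark.parametrize("tau, q10", [(-1.0, 3.0), (0.0, 3.0), (1.0, 0.0), (1.0, -2.0)])
    def test_rejects_nonpositive_parameters(self, tau, q10):
        with pytest.raises(vm.InvalidParameterError):
            vm.rescale_timescale_q10(tau, 23.0, 36.0, q10)


class TestTransitionWindow:
    def test_sigmoid_window_is_logit_inversion(self):
        v0, k = -30.0, 0.2
        gate = vm.GateSpec(
            name="m", role="activation",
            steady_state_form=vm.SigmoidSteadyState(v0, k),
            timescale_form=vm.ConstantTimescale(1.0),
        )
        v05, v95 = vm.transition_window(gate)
        width = math.log(19.0) / k
        assert v05 == pytest.approx(v0 - width)
        assert v95 == pytest.approx(v0 + width)

    def test_nav16_window(self, nav_gate):
        v05, v95 = vm.transition_window(nav_gate)
        assert v05 == pytest.approx(-17.0 - math.log(19.0) / 0.1565, abs=0.01)
        assert v95 == pytest.approx(-17.0 + math.log(19.0) / 0.1565, abs=0.01)
        assert v05 == pytest.approx(-35.8, abs=0.05)
        assert v95 == pytest.approx(1.8, abs=0.05)

    def test_inactivation_gate_flips_voltage_order(self):
        gate = vm.GateSpec(
            name="h", role="inactivation",
            steady_state_form=vm.SigmoidSteadyState(-50.0, -0.1),
            timescale_form=vm.ConstantTimescale(1.0),
        )
        v05, v95 = vm.transition_window(gate)
        # crossings are ordered by activity level, not voltage
        assert v05 > v95

    def test_rates_gate_window_matches_boltzmann(self):
        # alpha = exp(k(V-v0)/2), beta = exp(-k(V-v0)/2) gives exactly the
        # Boltzmann steady state 1/(1+exp(-k(V-v0)))
        v0, k = -40.0, 0.1
        rates = vm.RatePair(
            alpha=vm.HHRate("exponential", 1.0, 2.0 / k, v0),
            beta=vm.HHRate("exponential", 1.0, -2.0 / k, v0),
        )
        gate = vm.GateSpec(name="m", role="activation", rates=rates)
        v05, v95 = vm.transition_window(gate)
        width = math.log(19.0) / k
        assert v05 == pytest.approx(v0 - width, abs=1e-6)
        assert v95 == pytest.approx(v0 + width, abs=1e-6)


class TestRatePairConversion:
    def test_inf_tau_from_rates_on_grid(self):
        alpha = vm.HHRate("sigmoid", 0.5, -10.0, -40.0)
        beta = vm.HHRate("exp_linear", 0.2, 8.0, -30.0)
        pair = vm.RatePair(alpha, beta)
        grid = np.linspace(-100, 60, 161)
        a, b = alpha(grid), beta(grid)
        np.testing.assert_allclose(pair.steady_state(grid), a / (a + b), rtol=1e-12)
        np.testing.assert_allclose(pair.timescale(grid), 1.0 / (a + b), rtol=1e-12)

    def test_exp_linear_removable_singularity(self):
        rate = vm.HHRate("exp_linear", 0.7, 5.0, -20.0)
        assert float(rate(-20.0)) == pytest.approx(0.7)
        # continuity across the singular point
        assert float(rate(-20.0 + 1e-7)) == pytest.approx(0.7, rel=1e-6)


class TestClassifyFast:
    def _gate(self, timescale):
        return vm.GateSpec(
            name="m", role="activation",
            steady_state_form=vm.SigmoidSteadyState(-40.0, 0.1),
            timescale_form=timescale,
        )

    def test_constant_tau_below_membrane_is_fast(self):
        assert vm.classify_fast(self._gate(vm.ConstantTimescale(1.0)), 5.0)

    def test_constant_tau_above_membrane_is_slow(self):
        assert not vm.classify_fast(self._gate(vm.ConstantTimescale(10.0)), 5.0)

    def test_endpoint_rule_ignores_interior_peak(self):
        # Gaussian bell peaking mid-window: endpoints ~2 and ~4 ms are both
        # below 5 ms, so the endpoint rule says fast even though the
        # interior peak (12 ms) exceeds the membrane time constant.
        v0, k = -40.0, 0.1
        width = math.log(19.0) / k
        tau = vm.GaussianTimescale(
            amplitude_ms=11.0, center_mv=v0, width_mv=width / 1.2, baseline_ms=1.0
        )
        gate = self._gate(tau)
        v05, v95 = vm.transition_window(gate)
        lo, hi = float(tau(v05)), float(tau(v95))
        assert lo < 5.0 and hi < 5.0  # endpoint values
        assert float(tau(v0)) > 5.0  # interior peak
        assert vm.classify_fast(gate, 5.0)
        assert not vm.classify_fast(gate, 5.0, strict=True)

    def test_q10_rescaling_changes_classification(self):
        gate = self._gate(vm.ConstantTimescale(4.0))
        assert vm.classify_fast(gate, 5.0, tau_scale=1.0)
        assert not vm.classify_fast(gate, 5.0, tau_scale=3.0)  # colder target


class TestChannelModel:
    def test_persistent_iff_no_inactivation_gate(self, nav16):
        assert nav16.persistent
        h = vm.GateSpec(
            name="h", role="inactivation",
            steady_state_form=vm.SigmoidSteadyState(-60.0, -0.1),
            timescale_form=vm.ConstantTimescale(2.0),
        )
        chan = vm.ChannelModel(id="x", ion="Na", gates=nav16.gates + (h,),
                               experiment_temperature_c=23.0)
        assert not chan.persistent

    def test_exponent_must_be_positive(self):
        with pytest.raises(vm.InvalidParameterError):
            vm.GateSpec(
                name="m", role="activation", exponent=0,
                steady_state_form=vm.SigmoidSteadyState(-40.0, 0.1),
                timescale_form=vm.ConstantTimescale(1.0),
            )
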