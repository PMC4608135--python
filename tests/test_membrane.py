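"""Nernst reversals, model assembly, the full ODE and its fast reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voltmem as vm
from tests.conftest import eq5_field
from voltmem.synthetic import SyntheticChannelSpec, generate_synthetic_channel


class TestNernst:
    @pytest.mark.parametrize(
        "c_in, c_out, z, temp, printed_mv",
        [
            (21.0, 10.0, 1, 23.0, -19),  # amphibian Na+
            (90.0, 0.2, 1, 23.0, -156),  # amphibian K+
            (60.0, 10.4, -1, 23.0, 45),  # amphibian Cl-
            (0.5, 0.2, 2, 23.0, -12),  # amphibian Ca++
            (15.0, 145.0, 1, 36.0, 60),  # mammalian Na+
            (10.0, 125.0, -1, 36.0, -67),  # mammalian Cl-
        ],
    )
    def test_rounds_to_printed_millivolt(self, c_in, c_out, z, temp, printed_mv):
        assert round(vm.nernst(c_in, c_out, z, temp)) == printed_mv

    def test_equal_concentrations_give_zero(self):
        assert vm.nernst(12.0, 12.0, 1, 36.0) == 0.0

    @given(
        c_in=st.floats(0.1, 200), c_out=st.floats(0.1, 200),
        z=st.sampled_from([-2, -1, 1, 2]), temp=st.floats(0, 40),
    )
    @settings(deadline=None, derandomize=True)
    def test_antisymmetry_and_valence_scaling(self, c_in, c_out, z, temp):
        e = vm.nernst(c_in, c_out, z, temp)
        assert vm.nernst(c_out, c_in, z, temp) == pytest.approx(-e, abs=1e-12)
        assert vm.nernst(c_in, c_out, 2 * z, temp) == pytest.approx(e / 2.0)

    @pytest.mark.parametrize("c_in, c_out, z", [(0.0, 1.0, 1), (1.0, -1.0, 1), (1.0, 1.0, 0)])
    def test_invalid_parameters(self, c_in, c_out, z):
        with pytest.raises(vm.InvalidParameterError):
            vm.nernst(c_in, c_out, z, 23.0)


class TestConditions:
    def test_mammalian_potassium_full_precision(self, mammalian):
        # the K+ gradient at 36 degC gives -89.70 mV; display rounding is
        # the caller's concern, dynamics always use full precision
        assert mammalian.reversal("K") == pytest.approx(-89.70, abs=0.01)

    def test_hcn_mixed_reversal_is_fixed_override(self, amphibian, mammalian):
        assert amphibian.reversal("NaK") == -78.0
        assert mammalian.reversal("NaK") == -15.0

    def test_unknown_species_errors(self, amphibian):
        with pytest.raises(vm.AssemblyError, match="Mg"):
            amphibian.reversal("Mg")

    def test_temperature_sanity_bounds(self, amphibian):
        with pytest.raises(vm.InvalidParameterError):
            vm.IonicConditions(name="x", temperature_c=80.0, ions=amphibian.ions)


class TestBuildModel:
    def test_defaults_follow_ten_to_one_ratio(self, mammalian_nav16_model):
        (ch, gbar), = mammalian_nav16_model.channels
        assert gbar == pytest.approx(2.0)
        assert mammalian_nav16_model.leak_conductance == pytest.approx(0.2)
        assert round(mammalian_nav16_model.reversal_map["Na"]) == 60
        assert round(mammalian_nav16_model.leak_reversal) == -67

    def test_membrane_time_constant(self, mammalian):
        model = vm.build_model([], mammalian, capacitance=1.0, leak_conductance=0.2)
        assert model.tau_membrane == pytest.approx(5.0)

    def test_leak_only_fixed_point_is_leak_reversal(self, mammalian):
        model = vm.build_model([], mammalian)
        portrait = vm.phase_portrait(vm.reduce_fast(model))
        assert len(portrait.roots) == 1
        root = portrait.roots[0]
        assert root.stability == "stable"
        assert root.voltage == pytest.approx(model.leak_reversal, abs=1e-5)
        assert round(root.voltage) == -67

    def test_missing_species_names_channel(self, amphibian, nav16):
        import dataclasses

        odd = dataclasses.replace(nav16, id="oddball", ion="Mg")
        with pytest.raises(vm.AssemblyError, match="oddball"):
            vm.build_model([odd], amphibian)


class TestFullRhs:
    def test_leak_equilibrium(self, mammalian, nav16):
        model = vm.build_model([(nav16, 0.0)], mammalian)
        state = np.concatenate([[model.leak_reversal],
                                model.steady_gates(model.leak_reversal)])
        dv = vm.full_rhs(model, state)[0]
        assert dv == pytest.approx(0.0, abs=1e-12)

    def test_gate_derivatives_vanish_at_steady_state(self, mammalian_nav16_model):
        v = -30.0
        state = np.concatenate([[v], mammalian_nav16_model.steady_gates(v)])
        deriv = vm.full_rhs(mammalian_nav16_model, state)
        np.testing.assert_allclose(deriv[1:], 0.0, atol=1e-14)

    def test_voltage_derivative_matches_reduced_field(self, printed_mammalian_model):
        # at steady-state gates the full dV/dt is exactly the scalar field,
        # cross-checked against the independently coded reduced expression
        for v in (-100.0, -40.0, 0.0, 30.0):
            state = np.concatenate([[v], printed_mammalian_model.steady_gates(v)])
            dv = vm.full_rhs(printed_mammalian_model, state)[0]
            assert dv == pytest.approx(float(eq5_field(v)), abs=1e-12)
        # dV/dt at 0 mV is positive for the mammalian model (flows to +48)
        state = np.concatenate([[0.0], printed_mammalian_model.steady_gates(0.0)])
        assert vm.full_rhs(printed_mammalian_model, state)[0] > 0


class TestReduceFast:
    def test_leak_only_field_is_affine(self, mammalian):
        model = vm.build_model([], mammalian)
        f = vm.reduce_fast(model)
        grid = np.linspace(-140, 150, 59)
        expected = -model.leak_conductance * (grid - model.leak_reversal) / model.capacitance
        np.testing.assert_allclose(f(grid), expected, atol=1e-12)

    def test_matches_printed_field_pointwise(self, printed_mammalian_model):
        f = vm.reduce_fast(printed_mammalian_model)
        grid = np.linspace(-140, 150, 581)
        np.testing.assert_allclose(f(grid), eq5_field(grid), rtol=0, atol=1e-12)

    def test_amphibian_field_has_single_sign_change(self, printed_amphibian_model):
        f = vm.reduce_fast(printed_amphibian_model)
        grid = np.linspace(-140, 150, 2901)
        signs = np.sign(f(grid))
        assert int(np.sum(np.diff(signs) != 0)) == 1

    def test_slow_gate_refused_by_name(self, mammalian, nav16):
        slow = vm.load_channel("slow_inward_synthetic")
        model = vm.build_model([nav16, slow], mammalian)
        with pytest.raises(vm.ReductionError, match="slow_inward_synthetic.s"):
            vm.reduce_fast(model)
        field = vm.reduce_fast(model, force=True)
        assert field.approximate


class TestEquilibriumEquivalence:
    """Master oracle: (V*, x_inf(V*)) is a fixed point of the full system
    iff V* is a root of the fully-reduced field, regardless of timescales."""

    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_models(self, seed, mammalian):
        rng = np.random.default_rng(seed)
        channels = []
        for j in range(rng.integers(1, 4)):
            spec = SyntheticChannelSpec(
                id=f"syn{j}", ion=str(rng.choice(["Na", "K", "Cl"])),
                role=str(rng.choice(["activation", "inactivation"])),
                tau_ms=float(rng.uniform(0.5, 50.0)),
            )
            channels.append(generate_synthetic_channel(spec, int(rng.integers(2**31))))
        model = vm.build_model(channels, mammalian)
        field = vm.reduce_fast(model, force=True)
        portrait = vm.phase_portrait(field, grid_step=0.25)
        assert portrait.roots, "degenerate model with no equilibria"
        for root in portrait.roots:
            state = np.concatenate([[root.voltage], model.steady_gates(root.voltage)])
            deriv = vm.full_rhs(model, state)
            np.testing.assert_allclose(deriv, 0.0, atol=1e-5)
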