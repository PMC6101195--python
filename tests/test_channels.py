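"""Channel kinetics: steady states, time constants, current laws, SK scheme,
calcium pool. Oracles are direct evaluations of the defining expressions,
two-sided numerical limits at removable singularities, and a matrix-
exponential relaxation of the SK master equation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from stellatesim import channels as ch

V_GRID = np.linspace(-120.0, 60.0, 721)

ALL_GATES = sorted(ch._GATE_FUNCS)


class TestSteadyStates:
    def test_half_activation_at_tabulated_half_voltage(self):
        # sigmoidal gates evaluate to exactly 1/2 at their half-voltage
        assert ch.naf_m_inf(-26.1) == pytest.approx(0.5)
        assert ch.kdr_n_inf(-17.6) == pytest.approx(0.5)
        assert ch.naf_h_inf(-23.8) == pytest.approx(0.5)
        assert ch.nap_m_inf(-48.7) == pytest.approx(0.5)
        assert ch.hva_m_inf(-11.1) == pytest.approx(0.5)
        assert ch.lva_m_inf(-52.4) == pytest.approx(0.5)
        assert ch.km_m_inf(-40.0) == pytest.approx(0.5)

    def test_hcn_fast_fractional_power_value(self):
        # bracket equals 2 at V = -74.2, so the whole sigmoid is 2^-1.36
        assert ch.hcn_fast_inf(-74.2) == pytest.approx(2.0 ** -1.36, rel=1e-12)

    def test_ka_inactivation_limit(self):
        assert ch.ka_h_inf(-100.0) > 0.99
        assert ch.ka_h_inf(20.0) < 0.01

    def test_km_negative_slope_activates_with_depolarization(self):
        # the tabulated negative slope needs no sign fix-up
        assert ch.km_m_inf(-20.0) > ch.km_m_inf(-60.0)

    @pytest.mark.parametrize("key", ALL_GATES)
    def test_bounded_and_monotone(self, key):
        inf_fn, _ = ch._GATE_FUNCS[key]
        y = inf_fn(V_GRID)
        assert np.all((y >= 0.0) & (y <= 1.0))
        dy = np.diff(y)
        assert np.all(dy >= -1e-12) or np.all(dy <= 1e-12), f"{key} not monotone"


class TestTimeConstants:
    @pytest.mark.parametrize("key", ALL_GATES)
    def test_positive_finite_over_voltage_range(self, key):
        _, tau_fn = ch._GATE_FUNCS[key]
        tau = tau_fn(V_GRID)
        assert np.all(np.isfinite(tau)) and np.all(tau > 0)

    def test_hva_constants(self):
        assert float(ch.hva_m_tau(-60.0)) == pytest.approx(0.92)
        assert float(ch.hva_h_tau(0.0, f=1.0)) == pytest.approx(250.0)
        assert float(ch.hva_h_tau(0.0, f=1.2)) == pytest.approx(300.0)

    @pytest.mark.parametrize(
        "tau_fn, v_sing",
        [
            (ch.naf_m_tau, -33.0),
            (ch.naf_m_tau, -58.0),
            (ch.naf_h_tau, -48.0),
            (ch.naf_h_tau, -11.0),
            (ch.kdr_n_tau, -38.0),
            (ch.kdr_n_tau, -47.0),
            (ch.nap_m_tau, -38.0),
            (ch.ka_m_tau, -18.3),
            (ch.ka_h_tau, -58.0),
            (ch.lva_m_tau, -7.88),
        ],
    )
    def test_removable_singularities_match_two_sided_limits(self, tau_fn, v_sing):
        at = float(tau_fn(v_sing))
        eps = 1e-4
        lim = 0.5 * (float(tau_fn(v_sing - eps)) + float(tau_fn(v_sing + eps)))
        assert at == pytest.approx(lim, rel=1e-6)
        assert at > 0

    def test_f_scale_is_multiplicative(self):
        v = -55.0
        base = float(ch.kdr_n_tau(v, f=1.0))
        assert float(ch.kdr_n_tau(v, f=0.8)) == pytest.approx(0.8 * base)

    def test_hcn_fast_is_faster_than_slow_at_rest(self):
        assert float(ch.hcn_fast_tau(-65.0)) < float(ch.hcn_slow_tau(-65.0))


class TestGateSpecAPI:
    def test_registry_round_trip(self):
        spec = ch.default_gate_spec("NaF", "activation")
        assert spec.exponent == 3
        assert ch.gate_steady_state(spec, spec.vhalf) == pytest.approx(0.5)
        assert ch.gate_time_constant(spec, -60.0) > 0

    def test_printed_exponents(self):
        assert ch.GATE_EXPONENTS["KDR"]["activation"] == 4
        assert ch.GATE_EXPONENTS["HVA"]["activation"] == 3
        assert ch.GATE_EXPONENTS["LVA"]["activation"] == 2
        assert ch.GATE_EXPONENTS["KM"] == {"activation": 1}

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            ch.GateSpec("NaF", "activation", 3, -26.1, 0.0)


class TestCurrents:
    def test_ohmic_zero_at_reversal_and_with_closed_gates(self):
        assert ch.ohmic_current(3.2, 0.5**4, -90.0, ch.E_K) == 0.0
        assert ch.ohmic_current(3.2, 0.0, 10.0, ch.E_K) == 0.0

    def test_ohmic_direct_product(self):
        # NaF fully open at 0 mV: 4.2 mS/cm2 * (0 - 50) mV = -210 uA/cm2
        i = ch.ohmic_current(4.2, 1.0, 0.0, ch.E_NA)
        assert i == pytest.approx(-210.0)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            ch.ohmic_current(-1.0, 1.0, 0.0, ch.E_NA)

    def test_ghk_zero_at_nernst_potential(self):
        # solve GHK = 0 independently: E = (RT/2F) ln(co/ci) in the model's
        # thermal-voltage convention
        ci, co = 1e-4, 2.0
        e_ca = ch.GHK_VSLOPE * np.log(co / ci)
        assert float(ch.ghk_driving_force(e_ca, ci, co)) == pytest.approx(0.0, abs=1e-9)

    def test_ghk_inward_below_reversal(self):
        assert float(ch.ghk_current(0.18, 1.0, -60.0, 1e-4)) < 0.0

    def test_ghk_continuous_through_zero(self):
        at = float(ch.ghk_driving_force(0.0, 1e-4))
        near = 0.5 * (
            float(ch.ghk_driving_force(-1e-6, 1e-4))
            + float(ch.ghk_driving_force(1e-6, 1e-4))
        )
        assert at == pytest.approx(near, rel=1e-9)
        assert np.isfinite(at)

    def test_ghk_single_sign_change(self):
        v = np.linspace(-120, 200, 3000)
        s = np.sign(ch.ghk_driving_force(v, 1e-4))
        assert np.count_nonzero(np.diff(s)) == 1

    def test_lva_calcium_inactivation(self):
        assert ch.lva_calcium_inactivation(0.0) == 1.0
        assert ch.lva_calcium_inactivation(0.001) == pytest.approx(0.5)
        assert ch.lva_calcium_inactivation(1e-4) == pytest.approx(0.001 / 0.0011)
        ca = np.linspace(0, 0.01, 100)
        assert np.all(np.diff(ch.lva_calcium_inactivation(ca)) < 0)


class TestSKScheme:
    def test_generator_conserves_probability(self):
        q = ch.sk_rate_matrix(5e-4)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_closed_at_zero_calcium(self):
        assert ch.sk_open_fraction_ss(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_occupancies_sum_to_one(self):
        for ca in (0.0, 1e-4, 1e-3, 0.1):
            assert ch.sk_steady_state(ca).sum() == pytest.approx(1.0, abs=1e-9)

    def test_open_fraction_nondecreasing_in_calcium(self):
        cas = np.logspace(-6, -1, 40)
        fr = [ch.sk_open_fraction_ss(c) for c in cas]
        assert np.all(np.diff(fr) >= -1e-12)

    @pytest.mark.parametrize("ca", [1e-3, 1e-4, 2e-5])
    def test_null_space_matches_master_equation_relaxation(self, ca):
        # oracle: march the master equation to t -> infinity by matrix
        # exponential from a deterministic start in C1
        q = ch.sk_rate_matrix(ca)
        p0 = np.array([1.0, 0, 0, 0, 0, 0])
        p_inf = p0 @ expm(q * 1e7)
        assert np.allclose(ch.sk_steady_state(ca), p_inf, atol=1e-6)

    def test_rate_wiring_variants(self):
        # gamma-opening and delta-opening differ only in the open:closed
        # equilibrium ratio (gamma/delta vs delta/gamma)
        hi = ch.sk_open_fraction_ss(1e-4, opening="gamma")
        lo = ch.sk_open_fraction_ss(1e-4, opening="delta")
        assert hi > lo
        with pytest.raises(ValueError):
            ch.sk_rates("epsilon")

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            ch.sk_rate_matrix(-1.0)


class TestCalciumPool:
    def test_fixed_point_at_resting_calcium(self):
        assert ch.ca_derivative(ch.CA_REST, 0.0, 78.0) == 0.0

    def test_pure_decay(self):
        d = ch.ca_derivative(2 * ch.CA_REST, 0.0, 78.0)
        assert d == pytest.approx(-ch.CA_REST / 78.0)

    def test_inward_current_raises_calcium(self):
        assert ch.ca_derivative(ch.CA_REST, -1e-3, 78.0) > 0.0
        assert ch.ca_derivative(ch.CA_REST, +1e-3, 78.0) < 0.0


@settings(max_examples=50, deadline=None)
@given(v=st.floats(min_value=-120, max_value=60))
def test_all_gates_well_behaved_everywhere(v):
    for key, (inf_fn, tau_fn) in ch._GATE_FUNCS.items():
        y = float(inf_fn(v))
        tau = float(tau_fn(v))
        assert 0.0 <= y <= 1.0
        assert np.isfinite(tau) and tau > 0.0
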