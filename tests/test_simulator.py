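"""Model assembly, stimuli, and integration: passive closed forms, bitwise
determinism, cross-validation of the tabulated kernel against the
direct-evaluation reference integrator, and dt-convergence."""

import math

import numpy as np
import pandas as pd
import pytest

from stellatesim import channels
from stellatesim.measurements import impedance_profile, measure_rmp
from stellatesim.simulator import (
    MEMBRANE_AREA_CM2,
    CellModel,
    SimulationError,
    build_model,
    init_state,
    integrate_reference,
    make_chirp,
    make_gwn,
    make_step,
    make_zero,
    settle,
    simulate,
)


class TestModelAssembly:
    def test_lateral_cylinder_area(self):
        assert MEMBRANE_AREA_CM2 == pytest.approx(
            math.pi * 70e-4 * 75e-4, rel=1e-12
        )

    def test_passive_input_resistance_closed_form(self, passive_model):
        # R_in = R_m / area: 40 kOhm.cm2 over the cylinder's lateral surface
        expected = 40e3 / MEMBRANE_AREA_CM2 / 1e6
        assert passive_model.r_in_passive_MOhm == pytest.approx(expected, rel=1e-12)

    def test_negative_conductance_rejected(self, base_params):
        bad = base_params.copy()
        bad["g_naf"] = -1.0
        with pytest.raises(ValueError, match="g_naf"):
            build_model(bad)

    def test_missing_parameter_rejected(self, base_params):
        with pytest.raises(ValueError, match="missing"):
            build_model(base_params.drop("g_kdr"))


class TestStimuli:
    def test_chirp_sweeps_linearly(self):
        # instantaneous frequency at mid-sweep is half the final frequency:
        # count zero crossings in a narrow window around t = 7.5 s
        chirp = make_chirp()
        sel = (chirp.t > 7000.0) & (chirp.t <= 8000.0)
        wave = chirp.current_pA[sel]
        crossings = np.count_nonzero(np.diff(np.sign(wave)) != 0)
        assert crossings / 2.0 == pytest.approx(7.5, abs=0.5)

    def test_chirp_extrema(self):
        chirp = make_chirp()
        assert chirp.current_pA.max() == pytest.approx(20.0, abs=1e-3)
        assert chirp.current_pA.min() == pytest.approx(-20.0, abs=1e-3)

    def test_gwn_moments_and_reproducibility(self):
        rng = np.random.default_rng(0)
        g = make_gwn(100.0, 25000.0, 0.025, rng)
        assert g.current_pA.std() == pytest.approx(100.0, rel=0.01)
        assert abs(g.current_pA.mean()) < 1.0
        g2 = make_gwn(100.0, 25000.0, 0.025, np.random.default_rng(0))
        assert np.array_equal(g.current_pA, g2.current_pA)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            make_step(100.0, 0.0, -5.0)


class TestPassiveLimit:
    """With all active conductances zero the cell is an analytic RC circuit."""

    def test_rests_at_leak_reversal(self, passive_model):
        trace, state = settle(passive_model, 1000.0)
        assert state.v == pytest.approx(-77.0, abs=1e-6)
        assert trace.v.std() < 1e-9

    def test_step_response_is_exponential_with_rc_time_constant(self, passive_model):
        _, state = settle(passive_model, 200.0)
        trace, _ = simulate(passive_model, state, make_step(100.0, 0.0, 400.0, 400.0))
        r_in = passive_model.r_in_passive_MOhm
        defl = trace.v + 77.0
        steady = 100.0 * r_in * 1e-3  # pA * MOhm -> mV
        assert defl[-1] == pytest.approx(steady, rel=0.01)
        # fit log-linear decay of the charging residual -> tau = R_m C_m = 40 ms
        resid = steady - defl
        sel = (trace.t > 5) & (trace.t < 80)
        slope = np.polyfit(trace.t[sel], np.log(resid[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(40.0, rel=0.01)

    def test_sinusoid_response_matches_analytic_rc(self, passive_model):
        # steady-state sinusoidal drive: |Z(f)| = R / sqrt(1 + (2 pi f tau)^2)
        _, state = settle(passive_model, 400.0)
        r = passive_model.r_in_passive_MOhm
        dt = 0.025
        for f in (1.0, 3.0, 7.0, 12.0):
            n = int(round(3000.0 / dt))
            t = np.arange(1, n + 1) * dt
            wave = 20.0 * np.sin(2e-3 * np.pi * f * t)
            from stellatesim.simulator import Stimulus

            trace, _ = simulate(passive_model, state, Stimulus("sin", wave, dt))
            tail = trace.t > 1000.0
            amp = (trace.v[tail].max() - trace.v[tail].min()) / 2.0
            z = amp / 20.0 * 1e3  # mV/pA -> MOhm
            analytic = r / np.sqrt(1.0 + (2 * np.pi * f * 0.040) ** 2)
            assert z == pytest.approx(analytic, rel=0.01), f"{f} Hz"

    def test_chirp_impedance_profile_matches_analytic_rc(self, passive_model):
        # chirp-FFT estimate carries a few-percent leakage ripple at the top
        # of the band; the profile must match the RC form within that and the
        # phase must lag everywhere (no inductive region, Phi_L = 0)
        _, state = settle(passive_model, 400.0)
        trace, _ = simulate(passive_model, state, make_chirp())
        prof = impedance_profile(trace)
        r = passive_model.r_in_passive_MOhm
        analytic = r / np.sqrt(1.0 + (2 * np.pi * prof.f_Hz * 0.040) ** 2)
        assert np.allclose(prof.z_MOhm, analytic, rtol=0.035)
        # low-pass: the peak sits at the band floor and the profile decays
        f_r, q_r = prof.resonance()
        assert f_r < 1.0
        assert q_r == pytest.approx(1.0, abs=0.05)
        assert prof.z_MOhm[0] > 3 * prof.z_MOhm[-1]
        assert np.all(prof.phase_rad < 0.02)
        assert prof.inductive_phase() == pytest.approx(0.0, abs=1e-3)


class TestIntegration:
    def test_zero_stimulus_from_settled_state_is_constant(self, base_model, base_settled):
        _, state = base_settled
        trace, _ = simulate(base_model, state, make_zero(500.0))
        assert np.ptp(trace.v) < 0.01

    def test_bitwise_determinism(self, base_model, base_settled):
        _, state = base_settled
        stim = make_step(150.0, 0.0, 200.0, 200.0)
        t1, _ = simulate(base_model, state, stim)
        t2, _ = simulate(base_model, state, stim)
        assert np.array_equal(t1.v, t2.v)
        assert np.array_equal(t1.ca, t2.ca)

    def test_settling_twice_reaches_fixed_point(self, base_model, base_settled):
        _, state = base_settled
        trace2, state2 = settle(base_model, 1000.0, state=state)
        assert abs(state2.v - state.v) < 0.01
        assert np.ptp(trace2.v) < 0.01

    def test_input_state_not_mutated(self, base_model, base_settled):
        _, state = base_settled
        gates_before = state.gates.copy()
        simulate(base_model, state, make_step(400.0, 0.0, 100.0, 100.0))
        assert np.array_equal(state.gates, gates_before)

    def test_tabulated_kernel_matches_reference_integrator(self, base_model, base_settled):
        # the production path interpolates 0.01-mV kinetics tables; the
        # reference path evaluates every rate directly
        _, state = base_settled
        stim = make_step(-150.0, 0.0, 150.0, 150.0)
        fast, _ = simulate(base_model, state, stim)
        slow, _ = integrate_reference(base_model, state, stim)
        assert np.abs(fast.v - slow.v).max() < 0.005
        assert np.abs(fast.ca - slow.ca).max() < 1e-8

    def test_divergence_reported_with_time(self, base_params):
        # pathological drive must abort with a SimulationError, not NaNs
        model = build_model(base_params)
        _, state = settle(model, 100.0)
        huge = make_step(5e7, 0.0, 50.0, 50.0)
        with pytest.raises(SimulationError):
            simulate(model, state, huge)

    def test_sk_occupancies_conserved(self, base_model, base_settled):
        _, state = base_settled
        _, state2 = simulate(base_model, state, make_step(400.0, 0.0, 500.0, 500.0))
        assert state2.sk.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(state2.sk >= 0)

    def test_dt_convergence_of_smooth_measurements(self, base_model):
        # halving the step leaves the subthreshold measurements unchanged
        vals = {}
        for dt in (0.025, 0.0125):
            trace, state = settle(base_model, dt=dt)
            v_rmp, _ = measure_rmp(trace, (5000.0, 6000.0))
            sag_tr, _ = simulate(
                base_model, state, make_step(-200.0, 100.0, 1000.0, 1200.0, dt)
            )
            from stellatesim.measurements import measure_sag

            vals[dt] = (v_rmp, measure_sag(sag_tr, 100.0, 1000.0))
        assert vals[0.025][0] == pytest.approx(vals[0.0125][0], rel=0.01)
        assert vals[0.025][1] == pytest.approx(vals[0.0125][1], rel=0.01)


class TestTracePersistence:
    def test_hdf5_round_trip(self, base_model, base_settled, tmp_path):
        from stellatesim.simulator import Trace

        _, state = base_settled
        trace, _ = simulate(base_model, state, make_step(100.0, 0.0, 50.0, 50.0))
        path = tmp_path / "trace.h5"
        trace.to_hdf5(path, seed=1)
        back = Trace.from_hdf5(path)
        assert np.array_equal(back.v, trace.v)
        assert back.dt == trace.dt

    def test_frame_export(self, base_model, base_settled):
        _, state = base_settled
        trace, _ = simulate(base_model, state, make_step(100.0, 0.0, 10.0, 10.0))
        df = trace.to_frame()
        assert list(df.columns) == ["t_ms", "v_mV", "ca_mM", "i_pA"]
        assert len(df) == len(trace.v)
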