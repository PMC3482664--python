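"""Virtual-rig physics: exact integration, waveforms, feedback loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aecclamp import (
    BridgeSettings,
    CellCircuitState,
    InvalidArgumentError,
    RCParams,
    RigConfig,
    SpikeGenParams,
    StateError,
    VirtualRig,
    bridge_balance_display,
    gap_junction_current,
    run_closed_loop,
    sample_timestep,
    spike_generator_voltage,
    step_circuit,
)
from conftest import MODEL_RE, MODEL_RM, MODEL_TAUM


def noiseless(**kw):
    kw.setdefault("recording_noise_sd", 0.0)
    return RigConfig(**kw)


class TestStepCircuit:
    def test_rest_is_fixed_point(self):
        cfg = noiseless()
        st0 = CellCircuitState(0.0, cfg.resting_potential, 0.0)
        for dt in (0.01, 0.5, 100.0):
            st1 = step_circuit(st0, 0.0, dt, cfg)
            assert st1.v_electrode == 0.0
            assert st1.v_membrane == cfg.resting_potential

    def test_membrane_reaches_632_percent_at_tau(self):
        cfg = noiseless()
        st0 = CellCircuitState(0.0, cfg.resting_potential, 0.0)
        I = 0.2
        st1 = step_circuit(st0, I, MODEL_TAUM, cfg)
        deflection = st1.v_membrane - cfg.resting_potential
        assert deflection == pytest.approx(I * MODEL_RM * (1 - math.e**-1), rel=1e-12)

    def test_dc_steady_state_model_cell(self):
        # 0.1 nA held >> 5 tau: 5 mV electrode + 5 mV membrane deflection
        cfg = noiseless()
        st = CellCircuitState(0.0, cfg.resting_potential, 0.0)
        st = step_circuit(st, 0.1, 50 * MODEL_TAUM, cfg)
        assert st.v_electrode == pytest.approx(5.0, abs=1e-9)
        assert st.v_membrane - cfg.resting_potential == pytest.approx(5.0, abs=1e-9)
        assert st.v_raw - cfg.resting_potential == pytest.approx(10.0, abs=1e-9)

    @given(
        splits=st.lists(st.floats(0.05, 5.0), min_size=1, max_size=8),
        I=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_exact_integrator_subdivision_invariance(self, splits, I):
        """Subdividing a constant-current interval never changes the result."""
        cfg = noiseless()
        T = sum(splits)
        whole = step_circuit(
            CellCircuitState(1.0, -55.0, 0.0), I, T, cfg
        )
        stp = CellCircuitState(1.0, -55.0, 0.0)
        for dt in splits:
            stp = step_circuit(stp, I, dt, cfg)
        assert stp.v_electrode == pytest.approx(whole.v_electrode, rel=1e-12, abs=1e-12)
        assert stp.v_membrane == pytest.approx(whole.v_membrane, rel=1e-12, abs=1e-12)

    def test_closed_form_membrane_charging(self):
        cfg = noiseless()
        I, T = 0.3, 7.7
        st = step_circuit(CellCircuitState(0.0, cfg.resting_potential, 0.0), I, T, cfg)
        expected = cfg.resting_potential + I * MODEL_RM * (1 - math.exp(-T / MODEL_TAUM))
        assert st.v_membrane == pytest.approx(expected, rel=1e-14)

    def test_linearity_of_steady_state(self):
        cfg = noiseless()
        out = []
        for I in (0.1, 0.2):
            st = step_circuit(
                CellCircuitState(0.0, cfg.resting_potential, 0.0), I, 500.0, cfg
            )
            out.append(
                (st.v_electrode, st.v_membrane - cfg.resting_potential)
            )
        assert out[1][0] == pytest.approx(2 * out[0][0], rel=1e-9)
        assert out[1][1] == pytest.approx(2 * out[0][1], rel=1e-9)

    def test_polarized_electrode_doubles_R_for_negative_current(self):
        cfg = noiseless(polarization_ratio=2.0)
        st_pos = step_circuit(
            CellCircuitState(0.0, cfg.resting_potential, 0.0), 0.5, 500.0, cfg
        )
        st_neg = step_circuit(
            CellCircuitState(0.0, cfg.resting_potential, 0.0), -0.5, 500.0, cfg
        )
        assert st_pos.v_electrode == pytest.approx(0.5 * MODEL_RE, abs=1e-9)
        assert st_neg.v_electrode == pytest.approx(-0.5 * 2 * MODEL_RE, abs=1e-9)

    def test_pure_resistor_equilibrates_instantly(self):
        cfg = noiseless(electrode=RCParams(20.0, 0.0), membrane=None,
                        resting_potential=0.0)
        st = step_circuit(CellCircuitState(0.0, 0.0, 0.0), 1.0, 1e-6, cfg)
        assert st.v_electrode == 20.0

    def test_nonpositive_dt_rejected(self):
        cfg = noiseless()
        with pytest.raises(InvalidArgumentError):
            step_circuit(CellCircuitState(0.0, -60.0, 0.0), 0.0, 0.0, cfg)


class TestSpikeGenerator:
    def test_baseline_peak_and_continuity(self):
        p = SpikeGenParams(resting_potential=-62.0, spike_height=85.0,
                           spike_width=2.0, spike_times=(10.0,))
        assert spike_generator_voltage(p, 0.0) == -62.0
        assert spike_generator_voltage(p, 10.0) == pytest.approx(-62.0 + 85.0)
        # continuous at window edges: value -> rest
        eps = 1e-6
        assert spike_generator_voltage(p, 9.0 + eps) == pytest.approx(-62.0, abs=1e-6)
        assert spike_generator_voltage(p, 11.0 - eps) == pytest.approx(-62.0, abs=1e-6)

    def test_unimodal_positive_area(self):
        p = SpikeGenParams(spike_times=(5.0,))
        t = np.linspace(3.0, 7.0, 4001)
        v = spike_generator_voltage(p, t) - p.resting_potential
        assert np.trapezoid(v, t) > 0
        peak = np.argmax(v)
        assert np.all(np.diff(v[:peak]) >= -1e-12)
        assert np.all(np.diff(v[peak:]) <= 1e-12)

    def test_invalid_params(self):
        with pytest.raises(InvalidArgumentError):
            SpikeGenParams(spike_width=0.0)
        with pytest.raises(InvalidArgumentError):
            SpikeGenParams(spike_times=(5.0, 5.0))


class TestGapJunction:
    def test_zero_difference_gives_zero(self):
        assert gap_junction_current(500.0, -50.0, -50.0, 10.0) == 0.0

    def test_unit_arithmetic(self):
        # 500 nS x 10 mV = 5000 pA = 5 nA
        assert gap_junction_current(500.0, -50.0, -60.0, 10.0) == pytest.approx(5.0)

    def test_clipping_at_daq_limit(self):
        assert gap_junction_current(500.0, -20.0, -60.0, 10.0) == 10.0
        assert gap_junction_current(500.0, -100.0, -60.0, 10.0) == -10.0

    def test_negative_conductance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gap_junction_current(-1.0, 0.0, 0.0, 10.0)

    @given(g=st.floats(0.0, 1000.0), dv=st.floats(-30.0, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_linear_below_limit(self, g, dv):
        I = gap_junction_current(g, dv, 0.0, 1e9)
        assert I == pytest.approx(g * dv / 1000.0, rel=1e-12, abs=1e-12)


class TestBridgeBalance:
    def test_zero_bridge_is_identity(self):
        t = np.arange(1, 11, dtype=float)
        V = np.random.default_rng(0).normal(size=10)
        I = np.ones(10)
        assert np.array_equal(bridge_balance_display(V, I, t, 0.0, 0.5), V)

    def test_perfect_bridge_on_pure_resistor(self):
        # lag = 0, exact R on a purely resistive electrode: recovers V_m
        cfg = noiseless(electrode=RCParams(20.0, 0.0))
        rig = VirtualRig(cfg)
        I = np.concatenate([np.zeros(50), np.full(200, 0.4), np.zeros(100)])
        rec = rig.record(I, 0.1)
        out = bridge_balance_display(rec["V_raw"], rec["I"], rec["t"], 20.0, 0.0)
        np.testing.assert_allclose(out, rec["V_m"], atol=1e-10)

    def test_lag_leaves_transient_decaying_with_lag(self):
        # purely resistive electrode, current step at t0: residual artifact
        # is R*I*exp(-(t-t0)/lag)
        R, lag, I0, dt = 20.0, 0.4, 0.5, 0.01
        n = 400
        I = np.full(n, I0)
        t = dt * np.arange(1, n + 1)
        V_raw = R * I  # electrode drop only
        out = bridge_balance_display(V_raw, I, t, R, lag)
        expected = R * I0 * np.exp(-t / lag)
        np.testing.assert_allclose(out, expected, rtol=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bridge_balance_display([0.0], [0.0, 1.0], [0.0, 1.0], 10.0, 0.0)


class TestSampleTimestep:
    def test_zero_jitter_is_exact(self):
        rng = np.random.default_rng(0)
        assert sample_timestep(0.1, 0.0, rng) == 0.1

    def test_bounds_hold_over_many_draws(self):
        rng = np.random.default_rng(3)
        draws = np.array([sample_timestep(0.1, 0.3, rng) for _ in range(100_000)])
        assert draws.min() >= 0.07 and draws.max() <= 0.13
        assert draws.min() > 0

    def test_seed_reproducibility(self):
        a = [sample_timestep(0.1, 0.2, np.random.default_rng(7)) for _ in range(1)]
        b = [sample_timestep(0.1, 0.2, np.random.default_rng(7)) for _ in range(1)]
        assert a == b

    def test_invalid_jitter_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sample_timestep(0.1, 1.0, np.random.default_rng(0))
        with pytest.raises(InvalidArgumentError):
            sample_timestep(0.0, 0.1, np.random.default_rng(0))


class TestRecording:
    def test_vraw_is_vm_plus_ve(self):
        rig = VirtualRig(noiseless())
        rec = rig.record(np.random.default_rng(1).uniform(-0.5, 0.5, 500), 0.1)
        np.testing.assert_allclose(
            rec["V_raw"], rec["V_m"] + rec["Ve_true"], atol=1e-12
        )

    def test_vectorized_path_matches_stepwise(self):
        cfg = noiseless()
        I = np.random.default_rng(2).uniform(-0.5, 0.5, 300)
        rig = VirtualRig(cfg)
        rec = rig.record(I, 0.1)
        st = CellCircuitState(0.0, cfg.resting_potential, 0.0)
        for k in range(len(I)):
            st = step_circuit(st, I[k], 0.1, cfg)
        assert rec["Ve_true"][-1] == pytest.approx(st.v_electrode, rel=1e-10)
        assert rec["V_m"][-1] == pytest.approx(st.v_membrane, rel=1e-10)

    def test_identical_seeds_identical_recordings(self):
        cfg = RigConfig(rng_seed=5)
        a = VirtualRig(cfg).record(np.zeros(100), 0.1)
        b = VirtualRig(cfg).record(np.zeros(100), 0.1)
        assert np.array_equal(a["V_raw"], b["V_raw"])


class TestClosedLoop:
    def test_open_loop_at_rest(self):
        cfg = noiseless()
        rec = run_closed_loop(cfg, SpikeGenParams(spike_times=()), 0.0, None, 20.0)
        assert np.all(rec.I_injected == 0.0)
        np.testing.assert_allclose(rec.V_comp, rec.V_control, atol=1e-12)
        np.testing.assert_allclose(rec.V_control, cfg.resting_potential, atol=1e-12)

    def test_control_channel_equals_membrane_exactly(self):
        cfg = RigConfig(rng_seed=3, timestep_jitter_fraction=0.1)
        sg = SpikeGenParams(spike_times=(10.0,))
        rec = run_closed_loop(cfg, sg, 100.0, None, 30.0)
        # V_raw - Ve_true == V_control up to the recording noise on V_raw
        resid = rec.V_raw - rec.Ve_true - rec.V_control
        assert np.abs(resid).max() < 6 * cfg.recording_noise_sd

    def test_seed_determinism(self):
        cfg = RigConfig(rng_seed=11, timestep_jitter_fraction=0.2)
        sg = SpikeGenParams(spike_times=(5.0, 15.0))
        a = run_closed_loop(cfg, sg, 300.0, None, 25.0)
        b = run_closed_loop(cfg, sg, 300.0, None, 25.0)
        for name in ("t", "dt", "I_injected", "V_raw", "V_control", "V_comp"):
            assert np.array_equal(getattr(a, name), getattr(b, name)), name

    def test_uncalibrated_compensator_rejected(self):
        from aecclamp.compensation import Compensator

        with pytest.raises(StateError):
            Compensator(None)

    def test_bridge_mode_runs_and_subtracts(self):
        cfg = noiseless(rng_seed=1)
        sg = SpikeGenParams(spike_times=(5.0,))
        rec = run_closed_loop(cfg, sg, 100.0, BridgeSettings(MODEL_RE, 0.2), 15.0)
        assert np.any(rec.Ve_est != 0.0)
        np.testing.assert_allclose(rec.V_comp, rec.V_raw - rec.Ve_est, atol=1e-12)
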