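import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from volamp.device_model import (
    CalibrationError,
    DeviceParams,
    DeviceState,
    PulseSpec,
    apply_set_pulse,
    decay,
    estimate_activation_energy,
    fit_time_constant,
    read_current,
    sample_device,
    set_gain,
    tau_effective,
    tau_of_duty,
    K_B_EV,
)

REF_PULSE = PulseSpec(4.5, 100e-6, "set")


def pulse_n(state, pulse, params, n):
    for _ in range(n):
        state = apply_set_pulse(state, pulse, params)
    return state


class TestSetPulse:
    def test_sixteen_pulse_anchor(self, params, fresh_state):
        state = pulse_n(fresh_state, REF_PULSE, params, 16)
        assert state.conductance(params) * 1e9 == pytest.approx(1200.0, rel=1e-9)

    def test_zero_pulses_is_baseline(self, params, fresh_state):
        assert fresh_state.conductance(params) == pytest.approx(55e-9)

    def test_eta16_matches_bisection_oracle(self, params):
        # independent 1-D root find on the closed-form 16-pulse map
        def residual(eta):
            return (
                params.g_off
                + (1 - (1 - eta) ** 16) * (params.g_on - params.g_off)
                - 1200e-9
            )

        eta_oracle = bisect(residual, 1e-9, 0.5, xtol=1e-15)
        assert params.eta16 == pytest.approx(eta_oracle, rel=1e-9)

    def test_potentiation_strictly_increases_w(self, params):
        state = DeviceState(w=0.5)
        assert apply_set_pulse(state, REF_PULSE, params).w > 0.5

    def test_saturated_state_stays_at_one(self, params):
        state = DeviceState(w=1.0)
        assert apply_set_pulse(state, REF_PULSE, params).w == 1.0

    def test_time_advances_by_width(self, params, fresh_state):
        assert apply_set_pulse(fresh_state, REF_PULSE, params).t == pytest.approx(100e-6)

    def test_width_scaling_first_order(self, params):
        # 10 us gain follows 1-(1-eta)^(1/10) of the 100 us calibration
        expected = 1 - (1 - params.eta16) ** 0.1
        assert set_gain(params, 4.5, 10e-6) == pytest.approx(expected, rel=1e-12)

    def test_uncalibrated_amplitude_raises(self, params, fresh_state):
        with pytest.raises(CalibrationError, match="amplitude"):
            apply_set_pulse(fresh_state, PulseSpec(2.0, 100e-6, "set"), params)

    def test_explicit_gain_overrides_calibration(self, params, fresh_state):
        out = apply_set_pulse(fresh_state, PulseSpec(2.0, 100e-6, "set"), params, gain=0.25)
        assert out.w == pytest.approx(0.25)

    def test_wrong_polarity_rejected(self, params, fresh_state):
        with pytest.raises(ValueError):
            apply_set_pulse(fresh_state, PulseSpec(1.5, 100e-6, "read"), params)


class TestDecay:
    def test_zero_dt_is_identity(self, params):
        state = DeviceState(w=0.7)
        assert decay(state, 0.0, params).w == pytest.approx(0.7)

    def test_one_tau_gives_e_inverse(self, params):
        state = DeviceState(w=1.0)
        assert decay(state, 40e-3, params).w == pytest.approx(math.exp(-1), rel=1e-12)

    @given(
        w=st.floats(0.0, 1.0),
        dt=st.floats(0.0, 1.0),
        split=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_semigroup_property(self, w, dt, split):
        params = DeviceParams()
        one = decay(DeviceState(w=w), dt, params)
        two = decay(decay(DeviceState(w=w), dt * split, params), dt * (1 - split), params)
        assert two.w == pytest.approx(one.w, rel=1e-12, abs=1e-300)

    def test_negative_dt_rejected(self, params):
        with pytest.raises(ValueError):
            decay(DeviceState(w=0.5), -1e-3, params)

    def test_temperature_accelerates_decay(self, params):
        assert tau_effective(params, temperature=423.0) < tau_effective(params)

    def test_duty_tau_map_endpoints(self, params):
        assert tau_of_duty(0.15, params) == pytest.approx(15e-3)
        assert tau_of_duty(0.85, params) == pytest.approx(40e-3)
        # strictly ordered even outside the measured anchors
        taus = [tau_of_duty(d, params) for d in (0.05, 0.10, 0.15, 0.20, 0.95)]
        assert taus == sorted(taus) and len(set(taus)) == 5
        assert all(t > 0 for t in taus)

    @given(w=st.floats(0.0, 1.0), dt=st.floats(0.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_conductance_stays_bounded(self, w, dt):
        params = DeviceParams()
        g = decay(DeviceState(w=w), dt, params).conductance(params)
        assert params.g_off <= g <= params.g_on


class TestReadCurrent:
    def test_baseline_read(self, params, fresh_state):
        # 55 nS x 1.5 V = 82.5 nA
        assert read_current(fresh_state, 1.5, params) == pytest.approx(82.5e-9, rel=1e-12)

    def test_rectification_ratio(self, params):
        state = DeviceState(w=0.3)
        fwd = read_current(state, 1.5, params)
        rev = read_current(state, -1.5, params)
        assert fwd / abs(rev) == pytest.approx(1e4, rel=1e-12)

    def test_linearity_in_voltage(self, params):
        state = DeviceState(w=0.2)
        assert read_current(state, 3.0, params) == pytest.approx(
            2 * read_current(state, 1.5, params), rel=1e-12
        )

    def test_zero_voltage_rejected(self, params, fresh_state):
        with pytest.raises(ValueError):
            read_current(fresh_state, 0.0, params)

    def test_read_is_non_perturbing(self, params):
        state = DeviceState(w=0.4)
        read_current(state, 1.5, params)
        assert state.w == 0.4


def synth_trace(tau, params, n=50, t_max=0.2, w0=0.5):
    t = np.linspace(0, t_max, n)
    g = params.g_off + w0 * np.exp(-t / tau) * (params.g_on - params.g_off)
    return np.column_stack([t, g])


class TestFitTimeConstant:
    @pytest.mark.parametrize("tau_ms", [40.0, 15.0])
    def test_noiseless_recovery(self, params, tau_ms):
        trace = synth_trace(tau_ms * 1e-3, params)
        assert fit_time_constant(trace) == pytest.approx(tau_ms * 1e-3, rel=1e-9)

    def test_noisy_recovery_within_5pct(self, params):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 0.2, 200)
        g = params.g_off + 0.5 * np.exp(-t / 40e-3) * (params.g_on - params.g_off)
        g = g * (1 + 0.01 * rng.standard_normal(200))
        tau = fit_time_constant(np.column_stack([t, g]))
        assert tau == pytest.approx(40e-3, rel=0.05)

    def test_baseline_trace_rejected(self, params):
        trace = [(0.0, params.g_off), (0.01, params.g_off), (0.02, params.g_off)]
        with pytest.raises(ValueError):
            fit_time_constant(trace)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_time_constant([(0.0, 1e-7), (0.01, 9e-8)])

    def test_inverts_decay_operation(self, params):
        # trace produced by repeated decay() calls, not the closed form
        state = DeviceState(w=0.8)
        rows = []
        for _ in range(40):
            rows.append((state.t, state.conductance(params)))
            state = decay(state, 5e-3, params)
        assert fit_time_constant(rows) == pytest.approx(params.tau_ref, rel=1e-9)


class TestActivationEnergy:
    def test_recovers_generating_value(self, params):
        temps = [323.0, 353.0, 383.0, 423.0]
        taus = [(T, tau_effective(params, temperature=T)) for T in temps]
        assert estimate_activation_energy(taus) == pytest.approx(0.21, rel=1e-9)

    def test_constant_tau_gives_zero(self):
        assert estimate_activation_energy([(300.0, 0.04), (350.0, 0.04)]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_point_matches_analytic_slope(self):
        t1, t2, tau1, tau2 = 300.0, 400.0, 0.04, 0.01
        analytic = K_B_EV * math.log(tau1 / tau2) / (1 / t1 - 1 / t2)
        assert estimate_activation_energy([(t1, tau1), (t2, tau2)]) == pytest.approx(
            analytic, rel=1e-12
        )

    def test_single_temperature_rejected(self):
        with pytest.raises(ValueError):
            estimate_activation_energy([(300.0, 0.04), (300.0, 0.041)])


class TestSampleDevice:
    def test_zero_cv_is_identity(self, params):
        p = DeviceParams(cv_spatial=0.0)
        assert sample_device(p, 1) is p

    def test_determinism(self, params):
        assert sample_device(params, 42) == sample_device(params, 42)

    def test_monte_carlo_cv(self, params):
        taus = np.array([sample_device(params, s).tau_ref for s in range(10_000)])
        cv = taus.std() / taus.mean()
        assert cv == pytest.approx(0.0387, rel=0.05)

    def test_sampled_params_valid(self, params):
        for s in range(50):
            p = sample_device(params, s)
            assert p.g_off < p.g_on and p.tau_ref > 0 and 0 < p.eta16 < 1
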