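"""Controller stage: step detection, the serial-elastic correction
angle, the PD cascade, and closed-loop behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exogait.controller import (ControllerError, GaitPhaseState, PDGains,
                                PDLoopState, SensorFrame, SpringConfig,
                                control_step, motor_correction,
                                motor_correction_signed, pd_velocity_loop,
                                scale_curve_to_limits, simulate_tracking)
from exogait.curves import DesiredCurve, FourierCurve
from exogait.synthetic import make_grf_trace


def frame(t=0.0, f_ham=0.0, f_rf=0.0, grf=0.0, **kw):
    return SensorFrame(t=t, f_ham=f_ham, f_rf=f_rf, grf=grf, **kw)


class TestGaitPhase:
    def test_detection_fires_at_threshold_crossing(self):
        """A GRF ramp triggers exactly when GRF first reaches 30 N."""
        state = GaitPhaseState()
        fired_at = None
        for i, g in enumerate(np.linspace(0, 100, 101)):
            state.update(frame(t=i * 0.01, grf=g))
            if state.last_touchdown_t is not None:
                fired_at = g
                break
        assert fired_at == 30.0

    def _run_steps(self, durations, state=None):
        """Feed synthetic steps with the given durations; 60% stance."""
        state = state or GaitPhaseState()
        t = 0.0
        for d in durations:
            n = int(round(d / 0.01))
            for i in range(n):
                in_stance = i < 0.6 * n
                state.update(frame(t=t, grf=500.0 if in_stance else 0.0))
                t += 0.01
        state.update(frame(t=t, grf=500.0))  # final touchdown
        return state

    def test_periodic_steps_estimate_duration(self):
        state = self._run_steps([1.2, 1.2])
        assert state.est_duration == pytest.approx(1.2, abs=1e-9)

    def test_five_step_window_mean(self):
        """Durations 1.0..1.5 s: estimate = mean of the last five = 1.3 s."""
        state = self._run_steps([1.0, 1.1, 1.2, 1.3, 1.4, 1.5])
        assert state.est_duration == pytest.approx(1.3, abs=1e-9)

    def test_phase_in_range_and_monotone_within_step(self):
        state = self._run_steps([1.0, 1.0])
        phases = []
        t = state._last_t
        for i in range(1, 90):
            ph = state.update(frame(t=t + i * 0.01, grf=500.0 if i < 60 else 0.0))
            phases.append(ph)
        assert all(0 <= p < 1 for p in phases)
        assert np.all(np.diff(phases) >= 0)

    def test_out_of_order_timestamps_rejected(self):
        state = GaitPhaseState()
        state.update(frame(t=1.0, grf=0.0))
        with pytest.raises(ControllerError):
            state.update(frame(t=0.5, grf=0.0))

    @given(thr_lo=st.floats(10, 100), extra=st.floats(1, 200),
           seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raising_threshold_never_adds_steps(self, thr_lo, extra, seed):
        grf = make_grf_trace(1.1, 6, noise_sd=30.0, seed=seed, rate=200.0)

        def count(threshold):
            st_ = GaitPhaseState(threshold=threshold)
            n = 0
            last = None
            for t, g in zip(grf.grid, np.clip(grf.values, 0, None)):
                st_.update(frame(t=t, grf=g))
                if st_.last_touchdown_t is not None and st_.last_touchdown_t != last:
                    n += 1
                    last = st_.last_touchdown_t
            return n

        assert count(thr_lo + extra) <= count(thr_lo)


class TestMotorCorrection:
    def test_tracking_equilibrium_is_zero(self):
        springs = SpringConfig(k_ham=2000.0, k_rf=1000.0, r_m=0.02)
        # F_d/k == F_HAM/k_HAM + F_RF/k_RF
        f = frame(f_ham=4.0, f_rf=3.0)
        f_d = springs.k_ham * (4.0 / 2000.0 + 3.0 / 1000.0)
        assert motor_correction(f_d, f, springs) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_substitution(self):
        """F_d=10 N, F_HAM=5, F_RF=2, all k=1000 N/m, r_m=0.02 -> 0.15 rad."""
        springs = SpringConfig(k_ham=1000.0, k_rf=1000.0, r_m=0.02)
        dth = motor_correction(10.0, frame(f_ham=5.0, f_rf=2.0), springs)
        assert dth == pytest.approx(0.15, abs=1e-12)

    @given(fd=st.floats(-30, 30), fh=st.floats(0, 30), fr=st.floats(0, 30),
           c=st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity_and_rm_scaling(self, fd, fh, fr, c):
        springs = SpringConfig(k_ham=1500.0, k_rf=1200.0, r_m=0.02)
        k = springs.k_ham if fd >= 0 else springs.k_rf
        base = motor_correction(fd, frame(f_ham=fh, f_rf=fr), springs,
                                active_k=k)
        scaled = motor_correction(c * fd, frame(f_ham=c * fh, f_rf=c * fr),
                                  springs, active_k=k)
        assert scaled == pytest.approx(c * base, rel=1e-9, abs=1e-12)
        big_rm = SpringConfig(k_ham=1500.0, k_rf=1200.0, r_m=0.04)
        halved = motor_correction(fd, frame(f_ham=fh, f_rf=fr), big_rm,
                                  active_k=k)
        assert halved == pytest.approx(base / 2, rel=1e-9, abs=1e-12)

    def test_signed_form_matches_eq_when_inactive_slack(self):
        springs = SpringConfig(k_ham=1000.0, k_rf=1000.0, r_m=0.02)
        f = frame(f_ham=5.0, f_rf=0.0)
        assert motor_correction_signed(8.0, f, springs) == pytest.approx(
            motor_correction(8.0, f, springs))


class TestPDCascade:
    def test_zero_error_at_rest_gives_zero(self):
        cmd = pd_velocity_loop(0.0, frame(), PDGains(), PDLoopState())
        assert cmd == 0.0

    def test_saturation_clamps(self):
        cmd = pd_velocity_loop(100.0, frame(), PDGains(saturation=50.0),
                               PDLoopState())
        assert cmd == 50.0

    def test_step_response_settles_on_motor_plant(self):
        """Default gains settle a first-order motor plant within 2%."""
        gains = PDGains()
        state = PDLoopState()
        theta, omega, dt = 0.0, 0.0, 0.001
        target = 0.38
        trace = []
        for i in range(2000):
            f = frame(t=i * dt, motor_angle=theta, motor_velocity=omega)
            cmd = pd_velocity_loop(target - theta, f, gains, state)
            omega += dt * (cmd - 0.5 * omega) / 0.02
            theta += dt * omega
            trace.append(theta)
        tail = np.array(trace[-500:])
        assert np.all(np.abs(tail - target) < 0.02 * target)
        assert np.max(np.abs(trace)) < 2 * target  # no divergence


class TestControlStep:
    def _curve(self, a0=0.0, a1=10.0):
        fc = FourierCurve(a0=a0, a=np.array([a1] + [0.0] * 7), b=np.zeros(8))
        return DesiredCurve(fourier=fc, force_scale=23.0)

    def test_zero_command_before_first_full_step(self):
        out = control_step(frame(t=0.0, grf=400.0), self._curve(),
                           SpringConfig(), PDGains(), GaitPhaseState(),
                           PDLoopState())
        assert out.command == 0.0 and out.phase is None

    def test_deterministic_replay(self, designed_curve):
        grf = make_grf_trace(1.2, 6, rate=200.0)
        logs = []
        for _ in range(2):
            logs.append(simulate_tracking(designed_curve, grf.values,
                                          grf.grid, SpringConfig(), PDGains()))
        np.testing.assert_array_equal(logs[0]["command"], logs[1]["command"])

    def test_closed_loop_tracks_desired_curve(self, designed_curve):
        """Realized spring-force difference correlates with the desired
        curve on synthetic slow-walk GRF."""
        grf = make_grf_trace(1.333, 10, rate=500.0)
        log = simulate_tracking(designed_curve, grf.values, grf.grid,
                                SpringConfig(), PDGains())
        locked = ~np.isnan(log["phase"])
        f_real = log["f_ham"][locked] - log["f_rf"][locked]
        r = np.corrcoef(f_real, log["f_d"][locked])[0, 1]
        assert r > 0.8

    def test_zero_curve_commands_decay(self):
        curve = self._curve(a0=0.0, a1=0.0)
        grf = make_grf_trace(1.2, 8, rate=200.0)
        log = simulate_tracking(curve, grf.values, grf.grid, SpringConfig(),
                                PDGains())
        assert np.max(np.abs(log["command"][-200:])) < 1e-6


class TestScaleToLimits:
    def _curve(self, amp):
        fc = FourierCurve(a0=0.0, a=np.array([amp] + [0.0] * 7), b=np.zeros(8))
        return DesiredCurve(fourier=fc, force_scale=max(amp, 23.0))

    def test_within_limit_unchanged(self):
        c = self._curve(10.0)
        out = scale_curve_to_limits(c, 23.0)
        assert out.fourier.a[0] == 10.0

    def test_uniform_halving(self):
        out = scale_curve_to_limits(self._curve(46.0), 23.0)
        assert out.fourier.a[0] == pytest.approx(23.0, rel=1e-9)

    def test_shape_preserved(self, designed_curve):
        big = DesiredCurve(
            fourier=FourierCurve(designed_curve.fourier.a0 * 4,
                                 designed_curve.fourier.a * 4,
                                 designed_curve.fourier.b * 4),
            force_scale=92.0)
        out = scale_curve_to_limits(big, 23.0)
        phi = np.arange(512) / 512
        orig = big.fourier(phi)
        scaled = out.fourier(phi)
        np.testing.assert_allclose(scaled / np.max(np.abs(scaled)),
                                   orig / np.max(np.abs(orig)), atol=1e-12)
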