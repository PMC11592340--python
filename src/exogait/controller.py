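"""Exosuit motor control: gait-phase tracking, serial-elastic force
correction, and the cascaded PD loop with an inner velocity loop.

One motor drives both artificial muscles antagonistically through serial
elastic elements: a positive motor rotation pulls the artificial HAM and
slackens the artificial RF, and vice versa.  The controller converts the
desired force F_d at the current gait phase into the motor correction
angle

    dTheta = (F_d / k - F_HAM / k_HAM - F_RF / k_RF) / r_m

where k is the stiffness of the currently active muscle's spring (HAM
spring when F_d pulls HAM, RF spring otherwise) and r_m the motor pulley
radius.  A cascaded PD (outer position loop feeding an inner velocity
loop) turns dTheta into the motor drive signal.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .curves import DesiredCurve


class ControllerError(ValueError):
    pass


@dataclass
class SpringConfig:
    """Serial-elastic parameters.

    Stiffnesses are in force/length.  The blocked-motor identification
    springs on the physical suit are nominally very soft (printed as
    3 N/m, plausibly 3 N/mm); both interpretations are accepted here —
    stiffness is simply a configuration value.
    """

    k_ham: float = 3000.0  # N/m
    k_rf: float = 3000.0  # N/m
    rest_length_ham: float = 0.30  # m
    rest_length_rf: float = 0.30  # m
    r_m: float = 0.02  # motor pulley radius, m

    def __post_init__(self) -> None:
        for name in ("k_ham", "k_rf", "rest_length_ham", "rest_length_rf", "r_m"):
            if getattr(self, name) <= 0:
                raise ControllerError(f"{name} must be > 0")


@dataclass
class SensorFrame:
    """One synchronized sensor sample."""

    t: float  # s
    f_ham: float  # N
    f_rf: float  # N
    grf: float  # N, vertical
    motor_angle: float = 0.0  # rad
    motor_velocity: float = 0.0  # rad/s

    def __post_init__(self) -> None:
        if self.grf < 0:
            raise ControllerError("GRF must be >= 0")


@dataclass
class PDGains:
    """Cascaded-loop gains: outer angle->velocity P, inner velocity PD."""

    kp_outer: float = 60.0  # (rad/s) per rad
    kp_vel: float = 4.0
    kd_vel: float = 0.001
    saturation: float = 50.0  # drive-signal clamp

    def __post_init__(self) -> None:
        if min(self.kp_outer, self.kp_vel, self.kd_vel) < 0 or self.saturation <= 0:
            raise ControllerError("gains must be >= 0 and saturation > 0")


@dataclass
class GaitPhaseState:
    """Step detector + phase estimator state.

    A touchdown is an upward crossing of the GRF threshold preceded by at
    least ``debounce_s`` of near-zero GRF (swing); the estimated cycle
    duration is the mean of up to the last five inter-touchdown intervals.
    """

    threshold: float = 30.0  # N
    debounce_s: float = 0.050
    low_grf: float = 5.0  # N; "foot off the floor"
    last_touchdown_t: float | None = None
    est_duration: float | None = None
    recent_step_durations: deque = field(default_factory=lambda: deque(maxlen=5))
    in_contact: bool = False
    _low_since: float | None = None
    _swing_ok: bool = False
    _last_t: float | None = None

    def update(self, frame: SensorFrame) -> float | None:
        """Advance with one frame; return current phase in [0,1) or None.

        Phase is undefined (None) until one full inter-touchdown interval
        has been observed.
        """
        if self._last_t is not None and frame.t < self._last_t:
            raise ControllerError(
                f"out-of-order timestamp {frame.t} after {self._last_t}")
        self._last_t = frame.t

        if frame.grf < self.low_grf:
            if self._low_since is None:
                self._low_since = frame.t
            # a qualifying swing interval arms the detector; qualification
            # depends only on low_grf, so raising the detection threshold
            # can never create extra detections
            if frame.t - self._low_since >= self.debounce_s:
                self._swing_ok = True
            self.in_contact = False
        else:
            self._low_since = None
        if frame.grf >= self.threshold:
            if not self.in_contact and (self._swing_ok or self.last_touchdown_t is None):
                if self.last_touchdown_t is not None:
                    self.recent_step_durations.append(
                        frame.t - self.last_touchdown_t)
                    self.est_duration = float(
                        np.mean(self.recent_step_durations))
                self.last_touchdown_t = frame.t
            self.in_contact = True
            self._swing_ok = False

        if self.est_duration is None or self.last_touchdown_t is None:
            return None
        eps = 1e-9
        phase = (frame.t - self.last_touchdown_t) / self.est_duration
        return float(np.clip(phase, 0.0, 1.0 - eps))


def update_gait_phase(
    state: GaitPhaseState, frame: SensorFrame
) -> tuple[GaitPhaseState, float | None]:
    """Functional wrapper over :meth:`GaitPhaseState.update`."""
    phase = state.update(frame)
    return state, phase


def motor_correction(
    f_d: float, frame: SensorFrame, springs: SpringConfig,
    active_k: float | None = None,
) -> float:
    """Motor correction angle dTheta (rad) for a desired force F_d.

    ``active_k`` defaults to the stiffness of the muscle the desired force
    commands: the HAM spring for F_d >= 0, the RF spring otherwise.
    """
    if active_k is None:
        active_k = springs.k_ham if f_d >= 0 else springs.k_rf
    if active_k <= 0:
        raise ControllerError("active stiffness must be > 0")
    return (
        f_d / active_k
        - frame.f_ham / springs.k_ham
        - frame.f_rf / springs.k_rf
    ) / springs.r_m


def motor_correction_signed(
    f_d: float, frame: SensorFrame, springs: SpringConfig,
) -> float:
    """Signed correction angle used in the closed loop.

    The measured spring stretches enter as their *difference*
    (HAM minus RF), matching the antagonistic single-motor layout where a
    positive rotation loads the HAM spring and unloads the RF spring:

        dTheta = (F_d / k_active - (F_HAM/k_HAM - F_RF/k_RF)) / r_m

    This is the per-side mirror of :func:`motor_correction` (the two
    coincide whenever the inactive muscle is slack and the active one
    matches the sign of F_d) and is stabilizing on both sides of the
    zero crossing, which the magnitude form is not.
    """
    active_k = springs.k_ham if f_d >= 0 else springs.k_rf
    stretch_diff = frame.f_ham / springs.k_ham - frame.f_rf / springs.k_rf
    return (f_d / active_k - stretch_diff) / springs.r_m


@dataclass
class PDLoopState:
    prev_vel_error: float = 0.0
    prev_t: float | None = None


def pd_velocity_loop(
    delta_theta: float, frame: SensorFrame, gains: PDGains,
    state: PDLoopState,
) -> float:
    """Cascaded PD: angle error -> velocity setpoint -> drive signal.

    The outer loop is proportional (velocity setpoint = kp_outer * angle
    error); the inner loop is PD on the velocity error, with the drive
    saturated at the configured limit.
    """
    vel_setpoint = gains.kp_outer * delta_theta
    vel_error = vel_setpoint - frame.motor_velocity
    if state.prev_t is None or frame.t <= state.prev_t:
        d_term = 0.0
    else:
        d_term = (vel_error - state.prev_vel_error) / (frame.t - state.prev_t)
    state.prev_vel_error = vel_error
    state.prev_t = frame.t
    cmd = gains.kp_vel * vel_error + gains.kd_vel * d_term
    return float(np.clip(cmd, -gains.saturation, gains.saturation))


@dataclass
class MotorCommand:
    delta_theta: float  # rad
    command: float  # drive signal after the PD cascade
    phase: float | None = None
    f_d: float = 0.0


def control_step(
    frame: SensorFrame,
    curve: DesiredCurve,
    springs: SpringConfig,
    gains: PDGains,
    phase_state: GaitPhaseState,
    pd_state: PDLoopState,
) -> MotorCommand:
    """One control tick: phase update -> F_d -> dTheta -> PD cascade.

    Before the first full step (phase undefined) the controller commands
    zero drive, letting the wearer walk freely on startup.
    """
    phase = phase_state.update(frame)
    if phase is None:
        return MotorCommand(delta_theta=0.0, command=0.0, phase=None, f_d=0.0)
    f_d = float(curve.force_at_phase(phase))
    dth = motor_correction_signed(f_d, frame, springs)
    cmd = pd_velocity_loop(dth, frame, gains, pd_state)
    return MotorCommand(delta_theta=dth, command=cmd, phase=phase, f_d=f_d)


def scale_curve_to_limits(curve: DesiredCurve, force_limit: float) -> DesiredCurve:
    """Uniformly rescale a desired curve into hardware force limits.

    Scaling (rather than saturating) preserves the identified waveform
    shape.  Curves already within the limit are returned unchanged.
    """
    if force_limit <= 0:
        raise ControllerError("force_limit must be > 0")
    phi = np.arange(2048) / 2048.0
    peak = float(np.max(np.abs(curve.fourier(phi))))
    if peak <= force_limit:
        return curve
    s = force_limit / peak
    from .curves import FourierCurve  # local import to avoid cycle at module load

    scaled = FourierCurve(a0=curve.fourier.a0 * s, a=curve.fourier.a * s,
                          b=curve.fourier.b * s)
    return DesiredCurve(fourier=scaled, force_scale=float(force_limit),
                        cycle_duration=curve.cycle_duration)


def simulate_tracking(
    curve: DesiredCurve,
    grf: np.ndarray,
    t: np.ndarray,
    springs: SpringConfig,
    gains: PDGains,
    motor_inertia: float = 0.02,
    motor_damping: float = 0.5,
) -> dict:
    """Closed-loop replay of the controller against a simple motor+spring
    plant.

    The plant integrates ``J w' = command - b w`` and maps motor angle to
    antagonistic spring forces (positive angle stretches the HAM spring,
    negative the RF spring).  Returns a dict of logged arrays: t, phase,
    f_d, f_ham, f_rf, delta_theta, command.
    """
    n = len(t)
    phase_state = GaitPhaseState()
    pd_state = PDLoopState()
    theta = 0.0
    omega = 0.0
    log = {k: np.zeros(n) for k in
           ("phase", "f_d", "f_ham", "f_rf", "delta_theta", "command")}
    log["t"] = np.asarray(t, dtype=float)
    for i in range(n):
        f_ham = springs.k_ham * springs.r_m * max(theta, 0.0)
        f_rf = springs.k_rf * springs.r_m * max(-theta, 0.0)
        frame = SensorFrame(t=float(t[i]), f_ham=f_ham, f_rf=f_rf,
                            grf=float(max(grf[i], 0.0)),
                            motor_angle=theta, motor_velocity=omega)
        out = control_step(frame, curve, springs, gains, phase_state, pd_state)
        dt = float(t[i + 1] - t[i]) if i + 1 < n else float(t[i] - t[i - 1])
        omega += dt * (out.command - motor_damping * omega) / motor_inertia
        theta += dt * omega
        log["phase"][i] = np.nan if out.phase is None else out.phase
        log["f_d"][i] = out.f_d
        log["f_ham"][i] = f_ham
        log["f_rf"][i] = f_rf
        log["delta_theta"][i] = out.delta_theta
        log["command"][i] = out.command
    return log
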