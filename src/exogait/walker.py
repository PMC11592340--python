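"""Desk-scale planar muscle-driven walking environment.

A deliberately small stand-in for a full musculoskeletal simulation that
honors the training-environment contract: a 44-element observation, 18
muscle activations as the per-timestep action, a velocity/effort reward,
termination after ten detected steps or when the center of mass drops
below 0.8 m, and exosuit emulation through hip/knee coordinate actuators
with 0.10 m and 0.05 m lever arms.

Mechanics: a planar 7-segment skeleton (trunk, and thigh/shank/foot per
leg) modeled as point masses at the segment endpoints joined by stiff
damped springs, with weak damped rotational springs at the joints, 9
muscle-like torque actuators per leg (first-order activation dynamics,
tau = 10 ms, torque = activation x F_max x constant moment arm, the
biarticular ones spanning two joints), spring-damper ground contact with
a bounded Coulomb friction law, and semi-implicit Euler integration at
0.001 s.  The compliant-skeleton formulation keeps every internal force
either conservative or dissipative, so the zero-activation energy
invariant holds by construction rather than by delicate bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .controller import GaitPhaseState, SensorFrame
from .curves import DesiredCurve, FourierCurve


def _cross2(u, v) -> float:
    """z component of the 2-D cross product."""
    return float(u[0] * v[1] - u[1] * v[0])

# node layout: pelvis, torso-top, then per leg knee, ankle, toe
NODE_NAMES = ("P", "T", "KL", "AL", "OL", "KR", "AR", "OR")
N_NODES = len(NODE_NAMES)

# muscle table: name -> (hip arm, knee arm, ankle arm, F_max).  Moment
# arms in m with flexion positive at the hip, extension positive at the
# knee, dorsiflexion positive at the ankle; biarticular muscles span two
# joints.
MUSCLE_TABLE = {
    "iliopsoas": (+0.05, 0.0, 0.0, 1500.0),
    "glut_max": (-0.06, 0.0, 0.0, 2000.0),
    "RF": (+0.04, +0.04, 0.0, 1200.0),
    "VAS": (0.0, +0.05, 0.0, 3000.0),
    "HAM": (-0.05, -0.04, 0.0, 2500.0),
    "bifemsh": (0.0, -0.04, 0.0, 800.0),
    "GAS": (0.0, -0.03, -0.04, 1500.0),
    "TA": (0.0, 0.0, +0.04, 800.0),
    "SOL": (0.0, 0.0, -0.05, 3500.0),
}
MUSCLE_NAMES = tuple(MUSCLE_TABLE)  # 9 per leg, left then right = 18


@dataclass
class RewardConfig:
    """Velocity/effort reward parameters.

    ``reward = v_min + (v - v_min) / max(eps, mean(a)) + r_alive`` under
    the default ``reward_form="divide"`` (the lower the mean activation,
    the bigger the reward); ``reward_form="one_minus"`` multiplies the
    velocity surplus by ``(1 - mean(a))`` instead.  Both forms agree that
    an aborted timestep at ``v = v_min`` earns exactly ``v_min`` and that
    surviving a timestep adds ``r_alive``.
    """

    v_min: float = 0.2  # m/s
    r_alive: float = 0.1
    effort_floor: float = 0.05
    reward_form: str = "divide"

    def __post_init__(self) -> None:
        if self.v_min <= 0 or self.r_alive < 0 or self.effort_floor <= 0:
            raise ValueError("invalid reward configuration")
        if self.reward_form not in ("divide", "one_minus"):
            raise ValueError(f"unknown reward_form {self.reward_form!r}")


def compute_reward(v: float, activations: np.ndarray, alive: bool,
                   cfg: RewardConfig | None = None) -> float:
    """Per-timestep reward from velocity, muscle effort, and survival."""
    cfg = cfg or RewardConfig()
    a = np.clip(np.asarray(activations, dtype=float), 0.0, 1.0)
    effort = float(np.mean(a)) if a.size else 0.0
    if cfg.reward_form == "divide":
        term = (v - cfg.v_min) / max(cfg.effort_floor, effort)
    else:
        term = (v - cfg.v_min) * (1.0 - effort)
    return float(cfg.v_min + term + (cfg.r_alive if alive else 0.0))


@dataclass
class ExoConfig:
    """Exosuit-as-coordinate-actuators emulation parameters."""

    hip_lever: float = 0.10  # m
    knee_lever: float = 0.05  # m
    kp: float = 1.0  # force-error -> torque-setpoint gain, per m of lever
    tracking_rate: float = 50.0  # 1/s, actuator torque tracking bandwidth
    force_limit: float = 23.0  # N, hardware force range

    def __post_init__(self) -> None:
        if self.hip_lever <= 0 or self.knee_lever <= 0:
            raise ValueError("lever arms must be > 0")


def apply_exo_assist(force_error: float, exo: ExoConfig | None = None
                     ) -> tuple[float, float]:
    """Torque setpoints (hip, knee) for one leg from the force error.

    ``force_error = F_d - (F_HAM_model - F_RF_model)``; the error is
    separated onto the two coordinate actuators through the lever arms,
    so the hip/knee setpoint ratio equals the lever ratio and both are
    linear in the error.  The actuator PD tracking happens downstream in
    the environment's dynamics.
    """
    exo = exo or ExoConfig()
    return (exo.kp * exo.hip_lever * force_error,
            exo.kp * exo.knee_lever * force_error)


class PlanarWalkerEnv:
    """Planar 7-segment, 18-muscle walking environment.

    Gym-like contract: ``reset(seed, randomize) -> obs`` (length 44),
    ``step(action) -> (obs, reward, done, info)`` with ``action`` the 18
    muscle excitations in [0, 1], advancing the dynamics by 0.001 s.
    ``set_run_params`` accepts the 20 run-level parameters (17 Fourier
    coefficients of the desired curve + 3 actuator PD gains) sampled per
    run by the hybrid policy.
    """

    dt = 0.001
    obs_dim = 44
    action_dim = 18

    # geometry (m) and node masses (kg)
    trunk_len = 0.60
    thigh_len = 0.44
    shank_len = 0.43
    foot_len = 0.15
    masses = np.array([20.0, 30.0, 7.0, 3.5, 1.5, 7.0, 3.5, 1.5])

    # compliant-skeleton and contact parameters
    k_seg = 4.0e4  # N/m
    c_seg = 300.0  # N s/m
    k_joint = 60.0  # N m/rad, weak passive joint centering
    c_joint = 3.0  # N m s/rad
    k_contact = 3.0e4  # N/m
    c_contact = 120.0  # N s/m; kept well inside the explicit-Euler
    #                    stability region for the lightest node
    mu_friction = 0.9
    tau_act = 0.010  # s, activation time constant

    max_steps_per_run = 10
    com_min = 0.8  # m
    max_episode_time = 20.0  # s, safety cap

    # nominal mid-step pose: (hip, knee, ankle) per leg, rad
    pose_left = (0.35, -0.15, 0.0)
    pose_right = (-0.25, -0.05, 0.0)

    def __init__(self, reward_config: RewardConfig | None = None,
                 exo_config: ExoConfig | None = None,
                 use_exo: bool = False):
        self.reward_config = reward_config or RewardConfig()
        self.exo_config = exo_config or ExoConfig()
        self.use_exo = use_exo
        self.curve: DesiredCurve | None = None
        self._edges = self._build_edges()
        self.reset(seed=0, randomize=False)

    # ------------------------------------------------------------------
    def _build_edges(self):
        idx = {n: i for i, n in enumerate(NODE_NAMES)}
        L = (self.trunk_len, self.thigh_len, self.shank_len, self.foot_len)
        edges = [(idx["P"], idx["T"], L[0])]
        for side in ("L", "R"):
            edges += [
                (idx["P"], idx[f"K{side}"], L[1]),
                (idx[f"K{side}"], idx[f"A{side}"], L[2]),
                (idx[f"A{side}"], idx[f"O{side}"], L[3]),
            ]
        return edges

    def _nominal_positions(self) -> np.ndarray:
        """Node positions for the mid-step pose, feet touching ground."""
        pos = np.zeros((N_NODES, 2))
        idx = {n: i for i, n in enumerate(NODE_NAMES)}

        def leg(hip, knee, ankle):
            # angles measured from straight-down vertical, flexion forward
            thigh_dir = np.array([np.sin(hip), -np.cos(hip)])
            shank_ang = hip + knee  # knee extension positive keeps shank aligned
            shank_dir = np.array([np.sin(shank_ang), -np.cos(shank_ang)])
            foot_dir = np.array([np.cos(shank_ang + ankle),
                                 np.sin(shank_ang + ankle)])
            k = thigh_dir * self.thigh_len
            a = k + shank_dir * self.shank_len
            o = a + foot_dir * self.foot_len
            return k, a, o

        kl, al, ol = leg(*self.pose_left)
        kr, ar, orr = leg(*self.pose_right)
        # place pelvis so the lower foot touches the ground
        floor = min(al[1], ol[1], ar[1], orr[1])
        pelvis = np.array([0.0, -floor + 0.0])
        pos[idx["P"]] = pelvis
        pos[idx["T"]] = pelvis + np.array([0.0, self.trunk_len])
        for name, v in (("KL", kl), ("AL", al), ("OL", ol),
                        ("KR", kr), ("AR", ar), ("OR", orr)):
            pos[idx[name]] = pelvis + v
        return pos

    # ------------------------------------------------------------------
    def reset(self, seed: int = 0, randomize: bool = False) -> np.ndarray:
        rng = np.random.default_rng(seed)
        self.pos = self._nominal_positions()
        self.vel = np.zeros_like(self.pos)
        if randomize:
            self.pos[:, :] += rng.uniform(-0.01, 0.01, size=self.pos.shape)
            self.vel[:, :] += rng.uniform(-0.05, 0.05, size=self.vel.shape)
            self.vel[:, 0] += rng.uniform(0.0, 0.3)
        self.act = np.zeros(18)
        self.time = 0.0
        self.steps_completed = 0
        self._phase_state = GaitPhaseState()
        self._phase: float | None = None
        self._foot_airborne = {"L": True, "R": True}
        self._exo_torques = np.zeros(4)  # hipL, kneeL, hipR, kneeR
        self._grf = {"L": 0.0, "R": 0.0}
        self._contact_forces()  # refresh GRF for the initial observation
        return self.build_observation()

    def set_run_params(self, params: np.ndarray) -> None:
        """Install run-level parameters: Fourier curve + actuator gains."""
        params = np.asarray(params, dtype=float)
        if params.size < 17:
            raise ValueError("need >= 17 run-level parameters")
        fc = FourierCurve(a0=float(params[0]), a=params[1:9], b=params[9:17])
        curve = DesiredCurve(fourier=fc,
                             force_scale=self.exo_config.force_limit)
        from .controller import scale_curve_to_limits

        self.curve = scale_curve_to_limits(curve, self.exo_config.force_limit)
        if params.size >= 20:
            # actuator gains, squashed positive
            self.exo_config.kp = float(np.exp(np.clip(params[17], -3, 3)))
            self.exo_config.tracking_rate = 50.0 * float(
                np.exp(np.clip(params[18], -2, 2)))

    # -- helpers --------------------------------------------------------
    def _joint_angles(self) -> dict:
        idx = {n: i for i, n in enumerate(NODE_NAMES)}
        p = self.pos
        out = {}
        for side in ("L", "R"):
            trunk = p[idx["T"]] - p[idx["P"]]
            thigh = p[idx[f"K{side}"]] - p[idx["P"]]
            shank = p[idx[f"A{side}"]] - p[idx[f"K{side}"]]
            foot = p[idx[f"O{side}"]] - p[idx[f"A{side}"]]

            def ang(u, v):
                return float(np.arctan2(_cross2(u, v), np.dot(u, v)))

            # hip: thigh relative to (downward) trunk axis
            out[f"hip_{side}"] = ang(-trunk, thigh)
            out[f"knee_{side}"] = ang(thigh, shank)
            out[f"ankle_{side}"] = ang(shank, foot) + np.pi / 2
        return out

    def _muscle_lengths(self, angles: dict) -> np.ndarray:
        """Normalized actuator-length proxies from joint angles."""
        nominal = {"L": self.pose_left, "R": self.pose_right}
        out = np.zeros(18)
        i = 0
        for side in ("L", "R"):
            h0, k0, a0 = nominal[side]
            dh = angles[f"hip_{side}"] - h0
            dk = angles[f"knee_{side}"] - k0
            da = angles[f"ankle_{side}"] - a0
            for name, (rh, rk, ra, _f) in MUSCLE_TABLE.items():
                # positive joint motion along the muscle's torque direction
                # shortens it
                out[i] = 1.0 - (rh * dh + rk * dk + ra * da) / 0.3
                i += 1
        return out

    def muscle_forces(self) -> np.ndarray:
        fmax = np.array([m[3] for m in MUSCLE_TABLE.values()])
        return self.act * np.concatenate([fmax, fmax])

    # foot nodes contribute to the per-side GRF; every node contacts the
    # ground so a collapsed model comes to rest instead of falling through
    _foot_nodes = {"AL": "L", "OL": "L", "AR": "R", "OR": "R"}

    def _contact_forces(self) -> np.ndarray:
        """Ground spring-damper + bounded Coulomb friction; updates GRF."""
        f = np.zeros_like(self.pos)
        self._grf = {"L": 0.0, "R": 0.0}
        for i, name in enumerate(NODE_NAMES):
            y, vy, vx = self.pos[i, 1], self.vel[i, 1], self.vel[i, 0]
            if y < 0.0:
                fn = -self.k_contact * y - self.c_contact * vy
                fn = max(fn, 0.0)
                ft = -self.mu_friction * fn * np.tanh(vx / 0.05)
                f[i, 1] += fn
                f[i, 0] += ft
                side = self._foot_nodes.get(name)
                if side is not None:
                    self._grf[side] += fn
        return f

    def _skeleton_forces(self) -> np.ndarray:
        f = np.zeros_like(self.pos)
        for i, j, L0 in self._edges:
            d = self.pos[j] - self.pos[i]
            dist = float(np.linalg.norm(d)) + 1e-12
            u = d / dist
            rel_v = float((self.vel[j] - self.vel[i]) @ u)
            mag = self.k_seg * (dist - L0) + self.c_seg * rel_v
            f[i] += mag * u
            f[j] -= mag * u
        return f

    def _apply_torque(self, f: np.ndarray, joint: int, node_a: int,
                      node_b: int, tau: float) -> None:
        """Pure torque between segments joint-a and joint-b (zero net force)."""
        for node, sign in ((node_a, +1.0), (node_b, -1.0)):
            r = self.pos[node] - self.pos[joint]
            L2 = float(r @ r) + 1e-9
            fv = sign * tau / L2 * np.array([-r[1], r[0]])
            f[node] += fv
            f[joint] -= fv

    def _joint_torque_forces(self, angles: dict) -> np.ndarray:
        f = np.zeros_like(self.pos)
        idx = {n: i for i, n in enumerate(NODE_NAMES)}
        nominal = {"L": self.pose_left, "R": self.pose_right}
        # joint: (pivot, distal node, proximal node)
        for s, side in enumerate(("L", "R")):
            h0, k0, a0 = nominal[side]
            tau_m = {"hip": 0.0, "knee": 0.0, "ankle": 0.0}
            for mi, (name, (rh, rk, ra, fmax)) in enumerate(
                    MUSCLE_TABLE.items()):
                a = self.act[9 * s + mi]
                tau_m["hip"] += a * fmax * rh
                tau_m["knee"] += a * fmax * rk
                tau_m["ankle"] += a * fmax * ra
            if self.use_exo:
                tau_m["hip"] += self._exo_torques[2 * s]
                tau_m["knee"] += self._exo_torques[2 * s + 1]
            joints = {
                "hip": (idx["P"], idx[f"K{side}"], idx["T"],
                        angles[f"hip_{side}"] - h0),
                "knee": (idx[f"K{side}"], idx[f"A{side}"], idx["P"],
                         angles[f"knee_{side}"] - k0),
                "ankle": (idx[f"A{side}"], idx[f"O{side}"], idx[f"K{side}"],
                          angles[f"ankle_{side}"] - a0),
            }
            for jn, (pivot, distal, proximal, dq) in joints.items():
                tau = tau_m[jn] - self.k_joint * dq
                # joint damping on relative rotation, approximated through
                # the distal node's tangential velocity
                r = self.pos[distal] - self.pos[pivot]
                L2 = float(r @ r) + 1e-9
                omega_rel = _cross2(r, self.vel[distal] - self.vel[pivot]) / L2
                tau -= self.c_joint * omega_rel
                self._apply_torque(f, pivot, distal, proximal, tau)
        return f

    def com(self) -> np.ndarray:
        return (self.masses[:, None] * self.pos).sum(axis=0) / self.masses.sum()

    def com_velocity(self) -> np.ndarray:
        return (self.masses[:, None] * self.vel).sum(axis=0) / self.masses.sum()

    def mechanical_energy(self) -> float:
        """Kinetic + gravitational + elastic (segments, joints, contact)."""
        ke = 0.5 * float((self.masses[:, None] * self.vel**2).sum())
        pe = 9.81 * float((self.masses * self.pos[:, 1]).sum())
        el = 0.0
        for i, j, L0 in self._edges:
            dist = float(np.linalg.norm(self.pos[j] - self.pos[i]))
            el += 0.5 * self.k_seg * (dist - L0) ** 2
        angles = self._joint_angles()
        nominal = {"L": self.pose_left, "R": self.pose_right}
        for side in ("L", "R"):
            h0, k0, a0 = nominal[side]
            el += 0.5 * self.k_joint * (
                (angles[f"hip_{side}"] - h0) ** 2
                + (angles[f"knee_{side}"] - k0) ** 2
                + (angles[f"ankle_{side}"] - a0) ** 2)
        for i in range(N_NODES):
            y = self.pos[i, 1]
            if y < 0:
                el += 0.5 * self.k_contact * y**2
        return ke + pe + el

    # ------------------------------------------------------------------
    def step(self, action: np.ndarray):
        action = np.asarray(action, dtype=float)
        if not np.all(np.isfinite(action)):
            raise ValueError("non-finite muscle activation")
        u = np.clip(action, 0.0, 1.0)
        if u.shape != (18,):
            raise ValueError("action must have 18 muscle activations")
        # first-order activation dynamics
        self.act += self.dt * (u - self.act) / self.tau_act
        self.act = np.clip(self.act, 0.0, 1.0)

        angles = self._joint_angles()
        if self.use_exo and self.curve is not None and self._phase is not None:
            f_d = float(self.curve.force_at_phase(self._phase))
            names = list(MUSCLE_TABLE)
            iham, irf = names.index("HAM"), names.index("RF")
            fmax = np.array([m[3] for m in MUSCLE_TABLE.values()])
            for s in range(2):
                f_ham = self.act[9 * s + iham] * fmax[iham]
                f_rf = self.act[9 * s + irf] * fmax[irf]
                e = f_d - (f_ham - f_rf)
                hip_sp, knee_sp = apply_exo_assist(e, self.exo_config)
                # first-order torque tracking ("PD" actuator dynamics)
                rate = self.exo_config.tracking_rate
                self._exo_torques[2 * s] += self.dt * rate * (
                    hip_sp - self._exo_torques[2 * s])
                self._exo_torques[2 * s + 1] += self.dt * rate * (
                    knee_sp - self._exo_torques[2 * s + 1])

        f = self._skeleton_forces()
        f += self._joint_torque_forces(angles)
        f += self._contact_forces()
        f[:, 1] -= 9.81 * self.masses

        self.vel += self.dt * f / self.masses[:, None]
        self.pos += self.dt * self.vel
        self.time += self.dt

        grf_total = self._grf["L"] + self._grf["R"]
        frame = SensorFrame(t=self.time, f_ham=0.0, f_rf=0.0,
                            grf=float(grf_total))
        prev_touchdown = self._phase_state.last_touchdown_t
        self._phase = self._phase_state.update(frame)
        step_event = (self._phase_state.last_touchdown_t is not None
                      and self._phase_state.last_touchdown_t != prev_touchdown)
        if step_event:
            self.steps_completed += 1

        com = self.com()
        v = float(self.com_velocity()[0])
        fell = com[1] < self.com_min
        done = (self.steps_completed >= self.max_steps_per_run or fell
                or self.time >= self.max_episode_time)
        reward = compute_reward(v, self.act, alive=not fell,
                                cfg=self.reward_config)
        info = {
            "grf_left": self._grf["L"], "grf_right": self._grf["R"],
            "velocity": v, "com": com.copy(),
            "step_event": step_event, "steps_completed": self.steps_completed,
            "phase": self._phase, "time": self.time,
            "exo_torques": self._exo_torques.copy(),
        }
        return self.build_observation(), reward, bool(done), info

    def build_observation(self) -> np.ndarray:
        """Pack the 44-element observation.

        Order: 18 muscle fiber-length proxies, 18 muscle forces (kN),
        body orientation (trunk angle, cos, sin), body velocity (CoM vx,
        vy, trunk angular velocity), vertical GRF right then left (N).
        The 18+18+3+3+2 decomposition is one documented reading of the
        stated constituents.
        """
        idx = {n: i for i, n in enumerate(NODE_NAMES)}
        angles = self._joint_angles()
        trunk = self.pos[idx["T"]] - self.pos[idx["P"]]
        theta = float(np.arctan2(trunk[0], trunk[1]))  # 0 = upright
        r = trunk
        L2 = float(r @ r) + 1e-9
        omega = _cross2(r, self.vel[idx["T"]] - self.vel[idx["P"]]) / L2
        vcom = self.com_velocity()
        obs = np.concatenate([
            self._muscle_lengths(angles),
            self.muscle_forces() / 1000.0,
            [theta, np.cos(theta), np.sin(theta)],
            [vcom[0], vcom[1], omega],
            [self._grf["R"], self._grf["L"]],
        ])
        assert obs.shape == (self.obs_dim,)
        return obs
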