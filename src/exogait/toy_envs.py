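"""Small bundled environments for exercising the PPO trainer quickly.

These are deliberately tiny tasks with the same gym-like contract as the
walking environment, used to demonstrate that the trainer learns at
desk-scale budgets: a 1-DoF "hopper-lite" hover task for the per-timestep
action head, and a curve-recovery inverse problem for the run-level
parameter head.
"""

from __future__ import annotations

import numpy as np

from .ppo import PolicyNets, TrainConfig


def hopper_setup(seed: int) -> tuple["HopperLite", PolicyNets, TrainConfig]:
    """Standard desk-scale training setup for the hover task.

    About 16k environment steps; the moderate learning rate keeps late
    training stable so learning progress is monotone in practice.
    """
    env = HopperLite()
    nets = PolicyNets(env.obs_dim, env.action_dim, 0, init_log_std=-1.0,
                      rng=np.random.default_rng(seed))
    cfg = TrainConfig(update_interval=512, minibatch_size=128,
                      learning_rate=5e-4, total_timesteps=512 * 32)
    return env, nets, cfg


def recovery_setup(target: np.ndarray, seed: int
                   ) -> tuple["CurveRecoveryEnv", PolicyNets, TrainConfig]:
    """Standard desk-scale setup for the curve-parameter inverse problem.

    A larger learning rate with a floored linear anneal first moves the
    run-level mean across parameter space quickly, then refines it.
    """
    env = CurveRecoveryEnv(target)
    nets = PolicyNets(env.obs_dim, env.action_dim, len(np.atleast_1d(target)),
                      init_log_std=0.0, rng=np.random.default_rng(seed))
    cfg = TrainConfig(update_interval=256, minibatch_size=64,
                      learning_rate=1e-2, lr_anneal=True,
                      total_timesteps=256 * 300)
    return env, nets, cfg


class HopperLite:
    """1-DoF vertical hover task.

    State: height and vertical velocity of a thruster-carried point mass.
    Action: one "muscle activation" in [0, 1] mapped to upward thrust.
    Reward favors staying near the 1 m target height with little effort;
    the episode ends on crashing (h < 0.2 m), flying away (h > 2.5 m), or
    after ``max_steps``.  Hover requires a sustained activation of about
    g / thrust_gain ~ 0.65.
    """

    obs_dim = 2
    action_dim = 1
    dt = 0.02
    thrust_gain = 15.0
    gravity = 9.81
    drag = 0.8
    target = 1.0
    max_steps = 200

    def reset(self, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        self.h = 1.0 + rng.uniform(-0.1, 0.1)
        self.v = rng.uniform(-0.1, 0.1)
        self.t = 0
        return self._obs()

    def _obs(self) -> np.ndarray:
        return np.array([self.h - self.target, self.v])

    def step(self, action):
        a = float(np.clip(np.asarray(action).ravel()[0], 0.0, 1.0))
        self.v += self.dt * (self.thrust_gain * a - self.gravity
                             - self.drag * self.v)
        self.h += self.dt * self.v
        self.t += 1
        crashed = self.h < 0.2 or self.h > 2.5
        done = crashed or self.t >= self.max_steps
        reward = 1.0 - abs(self.h - self.target) - 0.05 * a * a
        if crashed:
            reward -= 5.0
        return self._obs(), float(reward), bool(done), {"h": self.h}


class CurveRecoveryEnv:
    """Inverse problem for the run-level head: recover hidden curve
    parameters.

    Each run is a single timestep; the policy's run-level parameters
    (e.g. the 17 Fourier coefficients of a desired curve) are compared to
    a hidden target vector and the reward is the negative mean squared
    distance.  A policy that maximizes expected reward moves its
    run-level mean onto the target.
    """

    obs_dim = 2
    action_dim = 0

    def __init__(self, target: np.ndarray):
        self.target = np.asarray(target, dtype=float)
        self.params: np.ndarray | None = None

    def set_run_params(self, params: np.ndarray) -> None:
        self.params = np.asarray(params, dtype=float)

    def reset(self, seed: int = 0) -> np.ndarray:
        return np.array([1.0, 0.0])

    def step(self, action):
        if self.params is None:
            raise RuntimeError("run parameters not set")
        err = float(np.mean((self.params - self.target) ** 2))
        return np.array([1.0, 0.0]), -err, True, {"mse": err}
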