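"""Proximal policy optimization with TD + generalized advantage
estimation over a hybrid action space.

The policy has two heads: per-timestep actions (the 18 muscle
activations in the walking environment) and run-level parameters (the
17 Fourier coefficients of the desired curve plus coordinate-actuator PD
gains), drawn once at the start of each run and held constant until the
next reset.  The combined log-probability of a transition is the
muscle-action log-probability plus, on the run's first transition only,
the run-parameter log-probability.

Environments follow a small gym-like contract: ``reset(seed) -> obs``,
``step(action) -> (obs, reward, done, info)``, and — if they consume
run-level parameters — ``set_run_params(params)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (MLP, Adam, clip_grad_norm, gaussian_entropy,
                 gaussian_logpdf)


class PPOError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """PPO hyperparameters.

    ``update_interval`` counts environment timesteps between updates and
    ``reuse_epochs`` the number of passes over each batch, following the
    every-2048, reuse-ten-times training loop; the remaining values are
    standard PPO practice and are free parameters.
    """

    update_interval: int = 2048
    reuse_epochs: int = 10
    minibatch_size: int = 256
    clip_ratio: float = 0.2
    entropy_coef: float = 0.01
    grad_norm_clip: float = 0.5
    critic_l2: float = 1e-4
    vf_coef: float = 0.5
    gamma: float = 0.99
    gae_lambda: float = 0.95
    learning_rate: float = 3e-4
    lr_anneal: bool = False  # linearly decay lr to 0 over training
    total_timesteps: int = 40_960  # desk-scale default, far below paper scale

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_ratio < 1.0):
            raise PPOError("clip_ratio must lie in (0, 1)")
        for name in ("update_interval", "reuse_epochs", "minibatch_size",
                     "gamma", "gae_lambda", "learning_rate", "total_timesteps"):
            if getattr(self, name) <= 0:
                raise PPOError(f"{name} must be > 0")


class PolicyNets:
    """Actor (shared trunk, two output heads) + critic networks.

    Hidden layers default to two of 64 units each for both networks.
    State-independent per-dimension log standard deviations parameterize
    the two diagonal-Gaussian heads.
    """

    def __init__(self, obs_dim: int, step_dim: int, run_dim: int,
                 hidden: tuple[int, ...] = (64, 64),
                 init_log_std: float = 0.0,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.obs_dim, self.step_dim, self.run_dim = obs_dim, step_dim, run_dim
        self.actor = MLP(obs_dim, hidden, (step_dim, run_dim), rng)
        self.critic = MLP(obs_dim, hidden, (1,), rng)
        self.log_std_step = np.full(step_dim, float(init_log_std))
        self.log_std_run = np.full(run_dim, float(init_log_std))

    @property
    def all_params(self) -> list[np.ndarray]:
        return (self.actor.params + [self.log_std_step, self.log_std_run]
                + self.critic.params)

    def set_all_params(self, params: list[np.ndarray]) -> None:
        na = len(self.actor.params)
        self.actor.params = [p.copy() for p in params[:na]]
        self.log_std_step = params[na].copy()
        self.log_std_run = params[na + 1].copy()
        self.critic.params = [p.copy() for p in params[na + 2:]]

    def value(self, obs: np.ndarray) -> np.ndarray:
        return self.critic.forward(obs)[0][:, 0]

    def to_dict(self) -> dict:
        return {"actor": self.actor.to_dict(), "critic": self.critic.to_dict(),
                "log_std_step": self.log_std_step.tolist(),
                "log_std_run": self.log_std_run.tolist()}


@dataclass
class RunParamsCache:
    """Holds the run-level parameters between resets."""
    params: np.ndarray | None = None
    log_prob: float = 0.0
    fresh: bool = False


def sample_hybrid_action(
    nets: PolicyNets, obs: np.ndarray, cache: RunParamsCache,
    rng: np.random.Generator, deterministic: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """Sample the per-timestep action and (at run start) run parameters.

    Returns ``(step_action, raw_step, run_params, combined_log_prob,
    run_sampled)``.  Per-timestep actions are squashed into [0, 1] by
    clipping the Gaussian sample; the raw sample is returned alongside
    because log-probability bookkeeping (and hence the importance ratios
    in later updates) must use it.  If ``cache.params`` is ``None`` the
    run-level head is sampled at this observation and its log-probability
    is attributed to this (first) transition.
    """
    mu_step, mu_run = (m[0] for m in nets.actor.forward(obs))
    if deterministic:
        raw_step = mu_step.copy()
    else:
        raw_step = mu_step + np.exp(nets.log_std_step) * rng.standard_normal(
            nets.step_dim)
    logp = float(gaussian_logpdf(raw_step, mu_step, nets.log_std_step))
    run_sampled = False
    if cache.params is None:
        if deterministic:
            raw_run = mu_run.copy()
        else:
            raw_run = mu_run + np.exp(nets.log_std_run) * rng.standard_normal(
                nets.run_dim)
        cache.params = raw_run
        cache.log_prob = float(
            gaussian_logpdf(raw_run, mu_run, nets.log_std_run))
        run_sampled = True
        logp += cache.log_prob
    return (np.clip(raw_step, 0.0, 1.0), raw_step, cache.params, logp,
            run_sampled)


def compute_gae(
    rewards: np.ndarray, values: np.ndarray, dones: np.ndarray,
    gamma: float, lam: float, last_value: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """TD(lambda)-style generalized advantage estimation.

    ``delta_t = r_t + gamma * v_{t+1} * (1 - done_t) - v_t`` with
    ``A_t = sum_k (gamma lam)^k delta_{t+k}`` truncated at episode ends;
    ``v_{T}`` for a truncated final segment is ``last_value``.  Returns
    ``(advantages, returns)`` with ``returns = advantages + values``.
    """
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    dones = np.asarray(dones, dtype=bool)
    if not (len(rewards) == len(values) == len(dones)):
        raise PPOError("rewards, values, dones must have equal length")
    n = len(rewards)
    adv = np.zeros(n)
    gae = 0.0
    next_value = float(last_value)
    for t in range(n - 1, -1, -1):
        nonterminal = 0.0 if dones[t] else 1.0
        delta = rewards[t] + gamma * next_value * nonterminal - values[t]
        gae = delta + gamma * lam * nonterminal * gae
        adv[t] = gae
        next_value = values[t]
    return adv, adv + values


def _policy_loss_terms(nets: PolicyNets, batch: dict, cfg: TrainConfig):
    """Forward pass: per-sample new log-probs, ratio, and surrogate mask.

    Returns everything needed both for the loss value and for backprop.
    """
    cache_a: dict = {}
    mu_step, mu_run = nets.actor.forward(batch["obs"], cache_a)
    lp = gaussian_logpdf(batch["step_actions"], mu_step, nets.log_std_step)
    has_run = batch["has_run"]
    lp_run = np.zeros(len(lp))
    if nets.run_dim > 0 and has_run.any():
        lp_run_all = gaussian_logpdf(
            np.where(has_run[:, None], batch["run_actions"], 0.0),
            mu_run, nets.log_std_run)
        lp_run = np.where(has_run, lp_run_all, 0.0)
    lp_new = lp + lp_run
    ratio = np.exp(lp_new - batch["logp_old"])
    adv = batch["advantages"]
    unclipped = ratio * adv
    clipped = np.clip(ratio, 1.0 - cfg.clip_ratio, 1.0 + cfg.clip_ratio) * adv
    surr = np.minimum(unclipped, clipped)
    return cache_a, mu_step, mu_run, lp_new, ratio, unclipped, clipped, surr


def loss_and_grads(nets: PolicyNets, batch: dict, cfg: TrainConfig):
    """Total PPO loss and analytic gradients for one minibatch.

    Loss = -mean(min(ratio A, clip(ratio) A)) - c_ent (H_step + H_run)
           + c_vf mean((V - R)^2) + c_l2 * sum(critic W^2)

    Returns ``(loss, grads, diagnostics)`` with grads aligned to
    ``nets.all_params``.
    """
    (cache_a, mu_step, mu_run, lp_new, ratio,
     unclipped, clipped, surr) = _policy_loss_terms(nets, batch, cfg)
    n = len(ratio)
    adv = batch["advantages"]
    has_run = batch["has_run"]

    entropy = gaussian_entropy(nets.log_std_step) + gaussian_entropy(
        nets.log_std_run)
    actor_loss = -float(np.mean(surr)) - cfg.entropy_coef * entropy

    # d actor_loss / d lp_new: only where the unclipped branch is active
    active = unclipped <= clipped
    g_lp = np.where(active, -ratio * adv / n, 0.0)

    var_step = np.exp(2.0 * nets.log_std_step)
    d_step = (batch["step_actions"] - mu_step) / var_step  # d lp / d mu
    dmu_step = g_lp[:, None] * d_step
    dls_step = (g_lp[:, None]
                * ((batch["step_actions"] - mu_step) ** 2 / var_step - 1.0)
                ).sum(axis=0) - cfg.entropy_coef * np.ones(nets.step_dim)

    if nets.run_dim > 0:
        var_run = np.exp(2.0 * nets.log_std_run)
        resid = np.where(has_run[:, None],
                         batch["run_actions"] - mu_run, 0.0)
        dmu_run = g_lp[:, None] * resid / var_run
        dls_run = (np.where(has_run[:, None], g_lp[:, None], 0.0)
                   * (resid ** 2 / var_run - 1.0)
                   ).sum(axis=0) - cfg.entropy_coef * np.ones(nets.run_dim)
    else:
        dmu_run = np.zeros((n, 0))
        dls_run = np.zeros(0)

    actor_grads, _ = nets.actor.backward(cache_a, [dmu_step, dmu_run])

    # critic: value MSE + L2 on weight matrices
    cache_c: dict = {}
    v = nets.critic.forward(batch["obs"], cache_c)[0][:, 0]
    verr = v - batch["returns"]
    critic_mse = float(np.mean(verr**2))
    dv = (cfg.vf_coef * 2.0 * verr / n)[:, None]
    critic_grads, _ = nets.critic.backward(cache_c, [dv])
    l2 = 0.0
    for i, p in enumerate(nets.critic.params):
        if p.ndim == 2:  # weights only
            l2 += float(np.sum(p * p))
            critic_grads[i] = critic_grads[i] + 2.0 * cfg.critic_l2 * p
    critic_loss = cfg.vf_coef * critic_mse + cfg.critic_l2 * l2

    loss = actor_loss + critic_loss
    grads = actor_grads + [dls_step, dls_run] + critic_grads
    if not np.isfinite(loss):
        raise PPOError("non-finite loss; diagnostics: "
                       f"ratio mean {np.mean(ratio):.3g}")
    diag = {
        "actor_loss": actor_loss, "critic_loss": critic_loss,
        "critic_mse": critic_mse, "entropy": entropy,
        "mean_ratio": float(np.mean(ratio)),
        "clip_fraction": float(np.mean(np.abs(ratio - 1.0) > cfg.clip_ratio)),
        "surrogate": float(np.mean(surr)),
        "surrogate_unclipped": float(np.mean(unclipped)),
    }
    return loss, grads, diag


def ppo_update(
    nets: PolicyNets, batch: dict, cfg: TrainConfig,
    optimizer: Adam | None = None, rng: np.random.Generator | None = None,
) -> dict:
    """Run ``reuse_epochs`` shuffled minibatch passes over one batch.

    Advantages are normalized once per update.  Returns aggregated
    diagnostics (means over minibatches).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    optimizer = optimizer or Adam(nets.all_params, lr=cfg.learning_rate)
    n = len(batch["obs"])
    adv = batch["advantages"]
    batch = dict(batch)
    batch["advantages"] = (adv - adv.mean()) / (adv.std() + 1e-8)
    diags: list[dict] = []
    for _ in range(cfg.reuse_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.minibatch_size):
            idx = order[start:start + cfg.minibatch_size]
            mb = {k: (v[idx] if isinstance(v, np.ndarray) else v)
                  for k, v in batch.items()}
            loss, grads, diag = loss_and_grads(nets, mb, cfg)
            diag["grad_norm"] = clip_grad_norm(grads, cfg.grad_norm_clip)
            params = nets.all_params
            optimizer.step(params, grads)
            nets.set_all_params(params)
            diags.append(diag)
    keys = diags[0].keys()
    return {k: float(np.mean([d[k] for d in diags])) for k in keys}


def train(env, nets: PolicyNets, cfg: TrainConfig, seed: int = 0):
    """Full PPO training loop; returns ``(nets, log)``.

    ``log`` is a list of per-update dicts with the mean return of episodes
    finished in each collection window plus optimizer diagnostics.
    Deterministic given ``seed`` and the environment's own seeding.
    """
    rng = np.random.default_rng(seed)
    optimizer = Adam(nets.all_params, lr=cfg.learning_rate)
    log: list[dict] = []
    cache = RunParamsCache()

    def do_reset():
        cache.params = None
        obs = env.reset(seed=int(rng.integers(2**31)))
        return np.asarray(obs, dtype=float)

    obs = do_reset()
    ep_return = 0.0
    ep_returns: list[float] = []
    n_updates = max(1, cfg.total_timesteps // cfg.update_interval)
    for update in range(n_updates):
        if cfg.lr_anneal:
            # linear decay with a 10% floor: coarse moves early, fine late
            optimizer.lr = cfg.learning_rate * max(0.1, 1.0 - update / n_updates)
        T = cfg.update_interval
        traj = {
            "obs": np.zeros((T, nets.obs_dim)),
            "step_actions": np.zeros((T, nets.step_dim)),
            "run_actions": np.zeros((T, nets.run_dim)),
            "has_run": np.zeros(T, dtype=bool),
            "logp_old": np.zeros(T),
            "rewards": np.zeros(T),
            "dones": np.zeros(T, dtype=bool),
        }
        values = np.zeros(T)
        for t in range(T):
            first_of_run = cache.params is None
            action, raw_step, run_params, logp, run_sampled = \
                sample_hybrid_action(nets, obs, cache, rng)
            if run_sampled and hasattr(env, "set_run_params"):
                env.set_run_params(run_params)
            traj["obs"][t] = obs
            traj["step_actions"][t] = raw_step
            if nets.run_dim > 0:
                traj["run_actions"][t] = run_params
            traj["has_run"][t] = first_of_run
            traj["logp_old"][t] = logp
            values[t] = float(nets.value(obs[None])[0])
            obs_next, reward, done, _info = env.step(action)
            traj["rewards"][t] = reward
            traj["dones"][t] = done
            ep_return += reward
            if done:
                ep_returns.append(ep_return)
                ep_return = 0.0
                obs = do_reset()
            else:
                obs = np.asarray(obs_next, dtype=float)
        last_value = 0.0 if traj["dones"][-1] else float(
            nets.value(obs[None])[0])
        adv, ret = compute_gae(traj["rewards"], values, traj["dones"],
                               cfg.gamma, cfg.gae_lambda, last_value)
        batch = {
            "obs": traj["obs"], "step_actions": traj["step_actions"],
            "run_actions": traj["run_actions"], "has_run": traj["has_run"],
            "logp_old": traj["logp_old"], "advantages": adv, "returns": ret,
        }
        diag = ppo_update(nets, batch, cfg, optimizer, rng)
        diag["update"] = update
        diag["mean_return"] = float(np.mean(ep_returns)) if ep_returns else np.nan
        diag["n_episodes"] = len(ep_returns)
        ep_returns = []
        log.append(diag)
    return nets, log
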