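"""End-to-end comparison pipeline: generate synthetic data, design the
empirical curve, (optionally) train the learned curve, replay both
controllers closed-loop, and run the sEMG comparison statistics.

The four experimental conditions are NE (no exosuit), NC (suit worn,
no assistance), Emp (empirical desired-force curve), and RL (curve
parameters learned by the policy's run-level head).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import analysis as ana
from . import synthetic as syn
from .config import RunConfig, config_echo
from .controller import PDGains, SpringConfig, simulate_tracking
from .curves import DesiredCurve, FourierCurve, design_empirical_curve
from .ppo import PolicyNets, TrainConfig, train
from .walker import ExoConfig, PlanarWalkerEnv, RewardConfig


class PipelineError(RuntimeError):
    pass


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


@_stage("design-curve")
def design_stage(cfg: RunConfig, seed: int) -> DesiredCurve:
    ham, rf = syn.make_force_templates(syn.GaitTemplateConfig(seed=seed))
    return design_empirical_curve(
        ham, rf, order=cfg.curve.order, sigma=cfg.curve.sigma,
        target_max_abs=cfg.curve.target_max_abs)


@_stage("train")
def train_stage(cfg: RunConfig, seed: int) -> DesiredCurve:
    """Short PPO run on the walker; the policy's run-level head provides
    the learned curve parameters (deterministic mean at the reset state)."""
    env = PlanarWalkerEnv(
        reward_config=RewardConfig(
            v_min=cfg.env.v_min, r_alive=cfg.env.r_alive,
            effort_floor=cfg.env.effort_floor,
            reward_form=cfg.env.reward_form),
        exo_config=ExoConfig(force_limit=cfg.curve.target_max_abs),
        use_exo=True)
    t = cfg.trainer
    nets = PolicyNets(env.obs_dim, env.action_dim, 20,
                      rng=np.random.default_rng(seed))
    tc = TrainConfig(
        update_interval=t.update_interval, reuse_epochs=t.reuse_epochs,
        minibatch_size=t.minibatch_size, learning_rate=t.learning_rate,
        clip_ratio=t.clip_ratio, entropy_coef=t.entropy_coef,
        gamma=t.gamma, gae_lambda=t.gae_lambda,
        total_timesteps=t.total_timesteps)
    nets, _log = train(env, nets, tc, seed=seed)
    mu_run = nets.actor.forward(env.reset(seed=seed))[1][0]
    fc = FourierCurve(a0=float(mu_run[0]), a=mu_run[1:9], b=mu_run[9:17])
    curve = DesiredCurve(fourier=fc, force_scale=cfg.curve.target_max_abs)
    from .controller import scale_curve_to_limits

    return scale_curve_to_limits(curve, cfg.curve.target_max_abs)


@_stage("simulate")
def tracking_stage(curve: DesiredCurve, cfg: RunConfig, step_duration: float,
                   seed: int) -> dict:
    """Closed-loop controller replay on synthetic GRF; returns tracking
    quality metrics (correlation of realized vs desired force)."""
    rate = 500.0
    grf = syn.make_grf_trace(step_duration, n_steps=10, seed=seed, rate=rate)
    springs = SpringConfig(**cfg.springs.model_dump())
    gains = PDGains(**cfg.gains.model_dump())
    log = simulate_tracking(curve, grf.values, grf.grid, springs, gains)
    locked = ~np.isnan(log["phase"])
    f_real = log["f_ham"][locked] - log["f_rf"][locked]
    f_des = log["f_d"][locked]
    if f_des.std() == 0 or f_real.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(f_real, f_des)[0, 1])
    return {"tracking_r": r,
            "rmse": float(np.sqrt(np.mean((f_real - f_des) ** 2))),
            "n_locked": int(locked.sum())}


def run_comparison(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; return (and optionally write) the report.

    The report carries, per condition: step duration, tracking quality
    (for the two assisted conditions), and per-muscle MAV/peak percent
    changes against NE, plus the ANOVA/post hoc statistics.  Deterministic
    given the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    seeds = {name: int(rng.integers(2**31))
             for name in ("generate", "curve", "train", "simulate")}

    effects = syn.default_condition_effects(cfg.generator.protocol)
    try:
        dataset = syn.make_emg_dataset(
            n_subjects=cfg.generator.n_subjects, effects=effects,
            n_steps=cfg.generator.n_steps, rate=cfg.generator.rate,
            noise_sd=cfg.generator.noise_sd,
            subject_sd=cfg.generator.subject_sd, seed=seeds["generate"])
    except Exception as e:
        raise PipelineError(f"stage 'generate' failed: {e}") from e

    emp_curve = design_stage(cfg, seeds["curve"])
    curves = {"Emp": emp_curve}
    if cfg.trainer.train:
        curves["RL"] = train_stage(cfg, seeds["train"])

    durations = {e.condition: e.step_duration for e in effects}
    tracking = {
        cond: tracking_stage(curve, cfg, durations[cond], seeds["simulate"])
        for cond, curve in curves.items()
    }

    try:
        summary, stats = ana.analyze_dataset(
            dataset, n_points=cfg.analysis.n_points,
            outlier_mads=cfg.analysis.outlier_mads,
            alpha=cfg.analysis.alpha, posthoc=cfg.analysis.posthoc)
    except Exception as e:
        raise PipelineError(f"stage 'analyze' failed: {e}") from e

    echo = config_echo(cfg)
    report = {
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(echo.encode()).hexdigest()[:16],
        "conditions": list(syn.CONDITIONS),
        "step_durations": durations,
        "tracking": tracking,
        "summary": summary.table.to_dict(orient="records"),
        "anova": stats.table.to_dict(orient="records"),
        "posthoc": stats.pairwise.to_dict(orient="records"),
        "curves": {c: json.loads(k.to_json()) for c, k in curves.items()},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        (out / "config_echo.json").write_text(echo)
        summary.table.to_csv(out / "summary.csv", index=False)
        stats.table.to_csv(out / "stats.csv", index=False)
        stats.pairwise.to_csv(out / "posthoc.csv", index=False)
    return report
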