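"""PPO trainer: GAE against a brute-force oracle, hybrid-action
log-probability bookkeeping, surrogate-objective identities, analytic
gradients against finite differences, and regularizer properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from exogait.nn import gaussian_entropy, gaussian_logpdf
from exogait.ppo import (PolicyNets, RunParamsCache, TrainConfig, compute_gae,
                         loss_and_grads, ppo_update, sample_hybrid_action)


def gae_bruteforce(rewards, values, dones, gamma, lam, last_value=0.0):
    """Independent oracle: explicit double-loop (gamma*lam)^k sums."""
    n = len(rewards)
    vnext = np.append(values[1:], last_value)
    deltas = rewards + gamma * vnext * (1 - dones) - values
    adv = np.zeros(n)
    for t in range(n):
        acc, w = 0.0, 1.0
        for k in range(t, n):
            acc += w * deltas[k]
            if dones[k]:
                break
            w *= gamma * lam
        adv[t] = acc
    return adv, adv + values


class TestGAE:
    def test_lambda_zero_is_one_step_td(self, rng):
        r = rng.normal(size=9)
        v = rng.normal(size=9)
        d = np.zeros(9, dtype=bool)
        d[4] = True
        adv, _ = compute_gae(r, v, d, 0.9, 0.0)
        vnext = np.append(v[1:], 0.0)
        delta = r + 0.9 * vnext * (1 - d) - v
        np.testing.assert_allclose(adv, delta, atol=1e-12)

    def test_undiscounted_reward_to_go(self):
        r = np.array([1.0, 2.0, 3.0])
        adv, ret = compute_gae(r, np.zeros(3), np.array([0, 0, 1], bool),
                               1.0, 1.0)
        np.testing.assert_allclose(adv, [6.0, 5.0, 3.0])
        np.testing.assert_allclose(ret, adv)

    def test_seven_step_random_sequence(self, rng):
        r = rng.normal(size=7)
        v = rng.normal(size=7)
        d = np.array([0, 0, 1, 0, 0, 0, 0], bool)
        adv, ret = compute_gae(r, v, d, 0.97, 0.9, last_value=0.31)
        a2, r2 = gae_bruteforce(r, v, d, 0.97, 0.9, 0.31)
        np.testing.assert_allclose(adv, a2, atol=1e-10)
        np.testing.assert_allclose(ret, r2, atol=1e-10)

    @given(n=st.integers(1, 20), seed=st.integers(0, 9999),
           gamma=st.floats(0.5, 1.0), lam=st.floats(0.0, 1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_up_to_length_20(self, n, seed, gamma, lam):
        r_ = np.random.default_rng(seed)
        rewards = r_.normal(size=n)
        values = r_.normal(size=n)
        dones = r_.random(n) < 0.3
        last = float(r_.normal())
        adv, ret = compute_gae(rewards, values, dones, gamma, lam, last)
        a2, r2 = gae_bruteforce(rewards, values, dones, gamma, lam, last)
        np.testing.assert_allclose(adv, a2, atol=1e-10)
        np.testing.assert_allclose(ret, r2, atol=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception):
            compute_gae(np.zeros(3), np.zeros(4), np.zeros(3, bool), 0.9, 0.9)


def make_batch(nets, n, rng, stale=0.0):
    """Roll a synthetic batch through the current policy.

    ``stale`` perturbs the stored log-probs to emulate an older policy.
    """
    obs = rng.normal(size=(n, nets.obs_dim))
    cache = RunParamsCache()
    batch = {"obs": obs,
             "step_actions": np.zeros((n, nets.step_dim)),
             "run_actions": np.zeros((n, nets.run_dim)),
             "has_run": np.zeros(n, dtype=bool),
             "logp_old": np.zeros(n),
             "advantages": rng.normal(size=n),
             "returns": rng.normal(size=n)}
    for i in range(n):
        if i % 5 == 0:
            cache.params = None  # new run begins
        _a, raw, p, lp, _ = sample_hybrid_action(nets, obs[i], cache, rng)
        batch["step_actions"][i] = raw
        batch["run_actions"][i] = p
        batch["has_run"][i] = (i % 5 == 0)
        batch["logp_old"][i] = lp + stale * rng.normal()
    return batch


class TestHybridSampling:
    def test_run_params_constant_within_run(self, rng):
        nets = PolicyNets(4, 3, 5, rng=rng)
        cache = RunParamsCache()
        obs = rng.normal(size=4)
        _, _, p0, _, sampled0 = sample_hybrid_action(nets, obs, cache, rng)
        assert sampled0
        for _ in range(6):
            _, _, p, _, sampled = sample_hybrid_action(
                nets, rng.normal(size=4), cache, rng)
            assert not sampled
            np.testing.assert_array_equal(p, p0)
        cache.params = None  # reset = new run
        _, _, p1, _, sampled1 = sample_hybrid_action(nets, obs, cache, rng)
        assert sampled1

    def test_deterministic_policy_returns_mean(self, rng):
        nets = PolicyNets(4, 3, 2, rng=rng)
        obs = rng.normal(size=4)
        mu_s, mu_r = (m[0] for m in nets.actor.forward(obs))
        a, raw, p, _, _ = sample_hybrid_action(nets, obs, RunParamsCache(),
                                               rng, deterministic=True)
        np.testing.assert_allclose(a, np.clip(mu_s, 0, 1))
        np.testing.assert_allclose(raw, mu_s)
        np.testing.assert_allclose(p, mu_r)

    def test_logprob_matches_scipy_density(self, rng):
        """Combined log-prob equals an independent normal-density sum."""
        nets = PolicyNets(4, 3, 2, rng=rng)
        obs = rng.normal(size=4)
        cache = RunParamsCache()
        rng2 = np.random.default_rng(777)
        _a, raw, p, lp, _ = sample_hybrid_action(nets, obs, cache, rng2)
        mu_s, mu_r = (m[0] for m in nets.actor.forward(obs))
        expected = (
            sstats.norm.logpdf(raw, mu_s, np.exp(nets.log_std_step)).sum()
            + sstats.norm.logpdf(p, mu_r, np.exp(nets.log_std_run)).sum())
        assert lp == pytest.approx(expected, abs=1e-6)


class TestSurrogate:
    def test_on_policy_ratios_are_one(self, rng):
        nets = PolicyNets(6, 4, 3, rng=rng)
        batch = make_batch(nets, 40, rng)
        _, _, diag = loss_and_grads(nets, batch, TrainConfig())
        assert diag["mean_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert diag["clip_fraction"] == 0.0

    def test_clipped_never_exceeds_unclipped(self, rng):
        nets = PolicyNets(6, 4, 3, rng=rng)
        for stale in (0.1, 0.5, 1.0):
            batch = make_batch(nets, 60, rng, stale=stale)
            _, _, diag = loss_and_grads(nets, batch, TrainConfig())
            assert diag["surrogate"] <= diag["surrogate_unclipped"] + 1e-12

    def test_entropy_nonnegative_for_unit_sigma(self, rng):
        nets = PolicyNets(4, 3, 2, rng=rng)
        assert gaussian_entropy(nets.log_std_step) >= 0
        assert gaussian_entropy(nets.log_std_run) >= 0

    def test_entropy_bonus_pushes_sigma_up(self, rng):
        """With a positive entropy coefficient the log-std gradient gains
        a constant negative (variance-increasing) term."""
        nets = PolicyNets(6, 4, 0, rng=rng)
        batch = make_batch(nets, 40, rng)
        cfg0 = TrainConfig(entropy_coef=0.0)
        cfg1 = TrainConfig(entropy_coef=0.05)
        _, g0, _ = loss_and_grads(nets, batch, cfg0)
        _, g1, _ = loss_and_grads(nets, batch, cfg1)
        i_ls = len(nets.actor.params)  # log_std_step slot
        np.testing.assert_allclose(g1[i_ls], g0[i_ls] - 0.05, atol=1e-12)

    def test_critic_l2_penalty_quadratic_in_weights(self, rng):
        nets = PolicyNets(6, 4, 0, rng=rng)
        batch = make_batch(nets, 30, rng)
        cfg = TrainConfig(critic_l2=1e-3, vf_coef=0.0)
        _, _, d1 = loss_and_grads(nets, batch, cfg)
        for p in nets.critic.params:
            if p.ndim == 2:
                p *= 2.0
        _, _, d2 = loss_and_grads(nets, batch, cfg)
        assert d2["critic_loss"] == pytest.approx(4 * d1["critic_loss"],
                                                  rel=1e-9)


class TestGradients:
    def test_matches_finite_differences(self, rng):
        """Analytic PPO gradients agree with central differences."""
        nets = PolicyNets(5, 3, 2, hidden=(8, 8), rng=rng)
        batch = make_batch(nets, 24, rng, stale=0.3)
        cfg = TrainConfig(entropy_coef=0.01, critic_l2=1e-4)

        def flatten(arrs):
            return np.concatenate([a.ravel() for a in arrs])

        def loss_at(flat):
            clone = PolicyNets(5, 3, 2, hidden=(8, 8),
                               rng=np.random.default_rng(0))
            shapes = [p.shape for p in nets.all_params]
            parts, k = [], 0
            for s in shapes:
                size = int(np.prod(s))
                parts.append(flat[k:k + size].reshape(s))
                k += size
            clone.set_all_params(parts)
            loss, _, _ = loss_and_grads(clone, batch, cfg)
            return loss

        loss, grads, _ = loss_and_grads(nets, batch, cfg)
        flat = flatten(nets.all_params)
        g_flat = flatten(grads)
        h = 1e-5
        check = np.random.default_rng(0).choice(len(flat), size=120,
                                                replace=False)
        for i in check:
            e = np.zeros_like(flat)
            e[i] = h
            fd = (loss_at(flat + e) - loss_at(flat - e)) / (2 * h)
            denom = max(abs(fd), abs(g_flat[i]), 1e-4)
            assert abs(fd - g_flat[i]) / denom < 1e-3, (
                f"coordinate {i}: analytic {g_flat[i]}, fd {fd}")


class TestUpdateAndDeterminism:
    def test_update_returns_finite_diagnostics(self, rng):
        nets = PolicyNets(6, 4, 3, rng=rng)
        batch = make_batch(nets, 64, rng)
        diag = ppo_update(nets, batch, TrainConfig(minibatch_size=32,
                                                   reuse_epochs=2),
                          rng=np.random.default_rng(0))
        assert np.isfinite(diag["actor_loss"])
        assert np.isfinite(diag["critic_loss"])
        assert diag["grad_norm"] >= 0

    def test_training_is_seed_deterministic(self):
        from exogait.toy_envs import HopperLite
        from exogait.ppo import train
        logs = []
        for _ in range(2):
            env = HopperLite()
            nets = PolicyNets(2, 1, 0, rng=np.random.default_rng(4))
            cfg = TrainConfig(update_interval=128, minibatch_size=64,
                              reuse_epochs=2, total_timesteps=384)
            _, log = train(env, nets, cfg, seed=11)
            logs.append(log)
        assert logs[0] == logs[1]
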