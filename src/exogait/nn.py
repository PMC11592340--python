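"""Minimal feed-forward networks with hand-written backpropagation.

The policy and value networks here are small (44 -> 64 -> 64 -> heads),
so a compact NumPy implementation with explicit gradients is used: a
multi-layer perceptron with tanh hidden units, optional multiple linear
output heads, an Adam optimizer, and global gradient-norm clipping.
Gradient correctness is pinned by finite-difference checks in the test
suite.
"""

from __future__ import annotations

import numpy as np


class MLP:
    """Tanh MLP with one or more linear output heads.

    Parameters are stored as a flat list (alternating W, b per layer,
    then per head).  ``forward`` caches activations; ``backward`` takes
    upstream gradients per head and returns parameter gradients in the
    same layout plus the gradient with respect to the input.
    """

    def __init__(self, in_dim: int, hidden: tuple[int, ...],
                 head_dims: tuple[int, ...], rng: np.random.Generator):
        self.in_dim = in_dim
        self.hidden = tuple(hidden)
        self.head_dims = tuple(head_dims)
        self.params: list[np.ndarray] = []
        prev = in_dim
        for h in hidden:
            # orthogonal-ish init scaled like standard PPO practice
            self.params.append(rng.normal(0, np.sqrt(2.0 / prev), (prev, h)))
            self.params.append(np.zeros(h))
            prev = h
        for d in head_dims:
            self.params.append(rng.normal(0, 0.01, (prev, d)))
            self.params.append(np.zeros(d))

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray, cache: dict | None = None):
        """Return list of head outputs for input batch x (n, in_dim)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        acts = [x]
        i = 0
        h = x
        for _ in self.hidden:
            W, b = self.params[i], self.params[i + 1]
            h = np.tanh(h @ W + b)
            acts.append(h)
            i += 2
        outs = []
        for _ in self.head_dims:
            W, b = self.params[i], self.params[i + 1]
            outs.append(h @ W + b)
            i += 2
        if cache is not None:
            cache["acts"] = acts
        return outs

    def __call__(self, x):
        return self.forward(x)

    # -- backward --------------------------------------------------------
    def backward(self, cache: dict, dheads: list[np.ndarray]):
        """Backprop upstream head gradients; return (param grads, dx)."""
        acts = cache["acts"]
        h_last = acts[-1]
        grads = [np.zeros_like(p) for p in self.params]
        i = 2 * len(self.hidden)
        dh = np.zeros_like(h_last)
        for j, _ in enumerate(self.head_dims):
            W = self.params[i]
            dout = dheads[j]
            if dout is None:
                i += 2
                continue
            grads[i] = h_last.T @ dout
            grads[i + 1] = dout.sum(axis=0)
            dh = dh + dout @ W.T
            i += 2
        for layer in range(len(self.hidden) - 1, -1, -1):
            li = 2 * layer
            W = self.params[li]
            a_in, a_out = acts[layer], acts[layer + 1]
            dz = dh * (1.0 - a_out**2)  # tanh'
            grads[li] = a_in.T @ dz
            grads[li + 1] = dz.sum(axis=0)
            dh = dz @ W.T
        return grads, dh

    # -- (de)serialization ----------------------------------------------
    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.params])

    def set_flat(self, flat: np.ndarray) -> None:
        k = 0
        for i, p in enumerate(self.params):
            self.params[i] = flat[k:k + p.size].reshape(p.shape).copy()
            k += p.size
        if k != flat.size:
            raise ValueError("flat parameter vector has wrong length")

    def to_dict(self) -> dict:
        return {
            "in_dim": self.in_dim, "hidden": list(self.hidden),
            "head_dims": list(self.head_dims),
            "params": [p.tolist() for p in self.params],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        net = cls(d["in_dim"], tuple(d["hidden"]), tuple(d["head_dims"]),
                  np.random.default_rng(0))
        net.params = [np.asarray(p, dtype=float) for p in d["params"]]
        return net


class Adam:
    """Adam over a list of parameter arrays (shared across nets)."""

    def __init__(self, params: list[np.ndarray], lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grad_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place to a global L2 norm cap; return the norm."""
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale
    return total


def gaussian_logpdf(x: np.ndarray, mean: np.ndarray,
                    log_std: np.ndarray) -> np.ndarray:
    """Sum of independent Gaussian log-densities over the last axis."""
    var = np.exp(2.0 * log_std)
    return np.sum(
        -0.5 * np.log(2.0 * np.pi) - log_std - 0.5 * (x - mean) ** 2 / var,
        axis=-1,
    )


def gaussian_entropy(log_std: np.ndarray) -> float:
    """Entropy of a diagonal Gaussian with the given per-dim log stds."""
    return float(np.sum(log_std + 0.5 * np.log(2.0 * np.pi * np.e)))
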