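"""NumPy neural-network primitives with hand-derived gradients.

Implements exactly what the sequence classifier needs: a forget-gate LSTM
layer with masking for variable-length batches, dense layers, masked
softmax and an Adam optimizer.  Gradients are written out analytically and
verified against finite differences in the test suite.

Conventions: batches are (B, T, D); per-layer parameters live in plain
dicts of float64 arrays; gate order inside the fused LSTM weight matrices
is input, forget, cell, output.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glorot_uniform",
    "orthogonal",
    "lstm_layer_init",
    "lstm_layer_forward",
    "lstm_layer_backward",
    "linear_init",
    "masked_softmax",
    "Adam",
]


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def lstm_layer_init(rng: np.random.Generator, input_size: int, hidden: int) -> dict[str, np.ndarray]:
    """Glorot input weights, orthogonal recurrent weights, forget bias 1."""
    wx = glorot_uniform(rng, input_size, hidden, shape=(input_size, 4 * hidden))
    wh = np.concatenate([orthogonal(rng, hidden) for _ in range(4)], axis=1)
    b = np.zeros(4 * hidden)
    b[hidden: 2 * hidden] = 1.0  # forget gate bias
    return {"wx": wx, "wh": wh, "b": b}


def lstm_layer_forward(
    x: np.ndarray, mask: np.ndarray, params: dict[str, np.ndarray]
) -> tuple[np.ndarray, dict]:
    """One LSTM layer over a padded batch.

    x: (B, T, D); mask: (B, T) with 1 at valid steps.  Hidden and cell
    states are zeroed at padded steps, so outputs past a sequence's true
    length are exactly 0 and padding cannot influence any valid output.
    Returns the hidden-state sequence (B, T, H) and a cache for backward.
    """
    b_sz, t_len, _ = x.shape
    h_dim = params["wh"].shape[0]
    h = np.zeros((b_sz, h_dim))
    c = np.zeros((b_sz, h_dim))
    hs = np.zeros((b_sz, t_len, h_dim))
    gates = np.zeros((b_sz, t_len, 4 * h_dim))
    cells = np.zeros((b_sz, t_len, h_dim))
    for t in range(t_len):
        z = x[:, t] @ params["wx"] + h @ params["wh"] + params["b"]
        i = _sigmoid(z[:, :h_dim])
        f = _sigmoid(z[:, h_dim: 2 * h_dim])
        g = np.tanh(z[:, 2 * h_dim: 3 * h_dim])
        o = _sigmoid(z[:, 3 * h_dim:])
        m = mask[:, t][:, None]
        c_new = (f * c + i * g) * m
        h = o * np.tanh(c_new) * m
        c = c_new
        hs[:, t] = h
        cells[:, t] = c
        gates[:, t] = np.concatenate([i, f, g, o], axis=1)
    cache = {"x": x, "mask": mask, "hs": hs, "cells": cells, "gates": gates, "params": params}
    return hs, cache


def lstm_layer_backward(d_hs: np.ndarray, cache: dict) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Backprop through time for one LSTM layer.

    d_hs: gradient w.r.t. the full hidden sequence (B, T, H).  Returns the
    gradient w.r.t. the layer input and the parameter gradients.
    """
    x, mask, hs, cells, gates = cache["x"], cache["mask"], cache["hs"], cache["cells"], cache["gates"]
    params = cache["params"]
    b_sz, t_len, h_dim = hs.shape
    dwx = np.zeros_like(params["wx"])
    dwh = np.zeros_like(params["wh"])
    db = np.zeros_like(params["b"])
    dx = np.zeros_like(x)
    dh_rec = np.zeros((b_sz, h_dim))
    dc = np.zeros((b_sz, h_dim))
    for t in range(t_len - 1, -1, -1):
        m = mask[:, t][:, None]
        i = gates[:, t, :h_dim]
        f = gates[:, t, h_dim: 2 * h_dim]
        g = gates[:, t, 2 * h_dim: 3 * h_dim]
        o = gates[:, t, 3 * h_dim:]
        c_t = cells[:, t]
        c_prev = cells[:, t - 1] if t > 0 else np.zeros_like(c_t)
        h_prev = hs[:, t - 1] if t > 0 else np.zeros_like(c_t)
        tc = np.tanh(c_t)
        dh = (d_hs[:, t] + dh_rec) * m
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        dcm = dc * m
        di = dcm * g
        df = dcm * c_prev
        dg = dcm * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
        )
        dwx += x[:, t].T @ dz
        dwh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ params["wx"].T
        dh_rec = dz @ params["wh"].T
        dc = dcm * f
    return dx, {"wx": dwx, "wh": dwh, "b": db}


def linear_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> dict[str, np.ndarray]:
    return {"w": glorot_uniform(rng, fan_in, fan_out), "b": np.zeros(fan_out)}


def masked_softmax(logits: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Softmax over the last axis with invalid positions forced to 0.

    Invalid logits are excluded from the normalization (the -inf
    convention); every row is assumed to contain at least one valid
    position.
    """
    neg = np.where(mask > 0, logits, -np.inf)
    neg = neg - neg.max(axis=-1, keepdims=True)
    e = np.exp(neg)
    e = np.where(mask > 0, e, 0.0)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
            m_hat = self.m[key] / (1 - self.beta1**self.t)
            v_hat = self.v[key] / (1 - self.beta2**self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    total = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total
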