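"""NumPy LSTM primitives: forward pass, backpropagation through time, Adam.

A single-layer LSTM with input, forget and output gates and a cell state,
read out many-to-one: a dense layer maps the final step's hidden state to the
output vector.  Gate pre-activations are ordered (input, forget, candidate,
output) inside the stacked weight matrices.  Everything runs in float64 —
the models are small and exact reproducibility beats speed here — and the
analytic gradients are held to finite-difference checks in the test suite.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

__all__ = [
    "init_params",
    "lstm_forward",
    "lstm_backward",
    "clip_grad_norm",
    "Adam",
]

Params = dict[str, np.ndarray]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_params(
    n_inputs: int,
    n_hidden: int,
    n_outputs: int,
    rng: np.random.Generator,
) -> Params:
    """Uniform(-k, k) initialization with k = 1/sqrt(n_hidden).

    The forget-gate bias starts at +1 so early training does not flush the
    cell state — the usual remedy for short training budgets.
    """
    k = 1.0 / math.sqrt(n_hidden)
    u = lambda *shape: rng.uniform(-k, k, size=shape)
    params: Params = {
        "Wx": u(n_inputs, 4 * n_hidden),
        "Wh": u(n_hidden, 4 * n_hidden),
        "b": u(4 * n_hidden),
        "Wy": u(n_hidden, n_outputs),
        "by": u(n_outputs),
    }
    params["b"][n_hidden : 2 * n_hidden] += 1.0
    return params


def lstm_forward(params: Mapping[str, np.ndarray], x: np.ndarray):
    """Run the LSTM over a batch of sequences.

    Parameters
    ----------
    params
        Weight dictionary from :func:`init_params`.
    x
        Input batch, shape (batch, n_steps, n_inputs).

    Returns
    -------
    y : (batch, n_outputs) readout from the final hidden state.
    cache : dict with per-step activations; ``cache["h"]`` has shape
        (batch, n_steps, n_hidden) and is what hidden-unit interpretation
        reads.  ``cache["c"]`` holds the cell states.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected (batch, steps, channels) input, got {x.shape}")
    B, T, D = x.shape
    H = params["Wh"].shape[0]
    if params["Wx"].shape[0] != D:
        raise ValueError(
            f"input has {D} channels but model expects {params['Wx'].shape[0]}"
        )

    hs = np.zeros((B, T, H))
    cs = np.zeros((B, T, H))
    gates = np.zeros((B, T, 4 * H))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        a = x[:, t] @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c = f * c + i * g
        h = o * np.tanh(c)
        gates[:, t, :H] = i
        gates[:, t, H : 2 * H] = f
        gates[:, t, 2 * H : 3 * H] = g
        gates[:, t, 3 * H :] = o
        cs[:, t] = c
        hs[:, t] = h
    y = h @ params["Wy"] + params["by"]
    cache = {"x": x, "h": hs, "c": cs, "gates": gates}
    return y, cache


def lstm_backward(
    params: Mapping[str, np.ndarray],
    cache: Mapping[str, np.ndarray],
    dy: np.ndarray,
) -> Params:
    """Backpropagate d(loss)/d(y) through the unrolled recurrence."""
    x, hs, cs, gates = cache["x"], cache["h"], cache["c"], cache["gates"]
    B, T, H = hs.shape

    grads: Params = {k: np.zeros_like(v) for k, v in params.items()}
    grads["Wy"] = hs[:, -1].T @ dy
    grads["by"] = dy.sum(axis=0)

    dh = dy @ params["Wy"].T
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H : 2 * H]
        g = gates[:, t, 2 * H : 3 * H]
        o = gates[:, t, 3 * H :]
        c = cs[:, t]
        c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H))
        h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H))

        tc = np.tanh(c)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev

        da = np.empty((B, 4 * H))
        da[:, :H] = di * i * (1.0 - i)
        da[:, H : 2 * H] = df * f * (1.0 - f)
        da[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
        da[:, 3 * H :] = do * o * (1.0 - o)

        grads["Wx"] += x[:, t].T @ da
        grads["Wh"] += h_prev.T @ da
        grads["b"] += da.sum(axis=0)

        dh = da @ params["Wh"].T
        dc = dc * f
    return grads


def clip_grad_norm(grads: Params, max_norm: float) -> float:
    """Scale all gradients in place so their global L2 norm <= max_norm."""
    total = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


class Adam:
    """Adam optimizer over a parameter dictionary."""

    def __init__(
        self,
        params: Params,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
    ) -> None:
        self.lr, self.beta1, self.beta2, self.epsilon = lr, beta1, beta2, epsilon
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.epsilon)
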