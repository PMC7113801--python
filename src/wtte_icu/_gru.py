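"""Low-level numerics for the masked GRU network.

Implements the forward pass, backpropagation through time and the Adam
update for the architecture: masking -> GRU(H units, tanh) -> dense(D units,
tanh) -> two linear heads (pre-link shape and scale outputs).  Masked steps
leave the recurrent state untouched, so the state read at the final step is
the state at the last unmasked step.

Gate equations (classic single-bias formulation):

    z = sigmoid(x Wz + h Uz + bz)          update gate
    r = sigmoid(x Wr + h Ur + br)          reset gate
    c = tanh(x Wc + (r*h) Uc + bc)         candidate state
    h' = z*h + (1-z)*c ;  h_t = m*h' + (1-m)*h

Everything operates on plain dicts of NumPy arrays; the sklearn-style
estimator in :mod:`wtte_icu.model` owns the training loop and the public API.
The analytic gradients are validated against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

GATE_NAMES = ("z", "r", "c")


def param_count(n_vars: int, gru_units: int, dense_units: int) -> int:
    """Learnable scalars: 3(I+H+1)H for the GRU, (H+1)D dense, (D+1)*2 heads."""
    return (
        3 * (n_vars + gru_units + 1) * gru_units
        + (gru_units + 1) * dense_units
        + (dense_units + 1) * 2
    )


def init_params(n_vars: int, gru_units: int, dense_units: int, rng: np.random.Generator,
                dtype=np.float64) -> dict:
    """Glorot-uniform kernels, zero biases."""
    def glorot(n_in, n_out):
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_in, n_out)).astype(dtype)

    p = {}
    for g in GATE_NAMES:
        p[f"W{g}"] = glorot(n_vars, gru_units)
        p[f"U{g}"] = glorot(gru_units, gru_units)
        p[f"b{g}"] = np.zeros(gru_units, dtype=dtype)
    p["Wd"] = glorot(gru_units, dense_units)
    p["bd"] = np.zeros(dense_units, dtype=dtype)
    # zero output kernel: the initial prediction is exactly the head bias,
    # i.e. the marginal fit installed by the estimator
    p["Wo"] = np.zeros((dense_units, 2), dtype=dtype)
    p["bo"] = np.zeros(2, dtype=dtype)
    return p


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward(params: dict, X: np.ndarray, step_ok: np.ndarray, keep_cache: bool = False):
    """Run the network on a batch.

    Parameters
    ----------
    X : (B, T, I) array, missing cells already replaced by 0.
    step_ok : (B, T) float array, 1.0 where the step is observed, 0.0 where
        masked (the recurrent state is carried through unchanged).

    Returns (raw, cache) where raw is the (B, 2) pre-link head output and
    cache holds the per-step activations needed for backprop (None unless
    ``keep_cache``).
    """
    B, T, _ = X.shape
    H = params["bz"].shape[0]
    dtype = params["Wz"].dtype
    h = np.zeros((B, H), dtype=dtype)
    cache = {"h_prev": [], "z": [], "r": [], "c": []} if keep_cache else None
    for t in range(T):
        x = X[:, t, :]
        m = step_ok[:, t][:, None]
        z = _sigmoid(x @ params["Wz"] + h @ params["Uz"] + params["bz"])
        r = _sigmoid(x @ params["Wr"] + h @ params["Ur"] + params["br"])
        c = np.tanh(x @ params["Wc"] + (r * h) @ params["Uc"] + params["bc"])
        h_new = z * h + (1.0 - z) * c
        if keep_cache:
            cache["h_prev"].append(h)
            cache["z"].append(z)
            cache["r"].append(r)
            cache["c"].append(c)
        h = m * h_new + (1.0 - m) * h
    d = np.tanh(h @ params["Wd"] + params["bd"])
    raw = d @ params["Wo"] + params["bo"]
    if keep_cache:
        cache["h_last"] = h
        cache["d"] = d
    return raw, cache


def backward(params: dict, X: np.ndarray, step_ok: np.ndarray, cache: dict,
             draw: np.ndarray) -> dict:
    """Gradients of the batch loss w.r.t. every parameter.

    ``draw`` is dLoss/draw at the head output, shape (B, 2).
    """
    B, T, _ = X.shape
    g = {k: np.zeros_like(v) for k, v in params.items()}

    d = cache["d"]
    h_last = cache["h_last"]
    g["Wo"] = d.T @ draw
    g["bo"] = draw.sum(axis=0)
    dd = draw @ params["Wo"].T
    da_d = dd * (1.0 - d * d)
    g["Wd"] = h_last.T @ da_d
    g["bd"] = da_d.sum(axis=0)
    dh = da_d @ params["Wd"].T

    for t in range(T - 1, -1, -1):
        m = step_ok[:, t][:, None]
        h_prev = cache["h_prev"][t]
        z, r, c = cache["z"][t], cache["r"][t], cache["c"][t]
        x = X[:, t, :]

        dh_new = dh * m
        dh_prev = dh * (1.0 - m)

        dz = dh_new * (h_prev - c)
        dc = dh_new * (1.0 - z)
        dh_prev = dh_prev + dh_new * z

        da_c = dc * (1.0 - c * c)
        rh = r * h_prev
        g["Wc"] += x.T @ da_c
        g["Uc"] += rh.T @ da_c
        g["bc"] += da_c.sum(axis=0)
        drh = da_c @ params["Uc"].T
        dr = drh * h_prev
        dh_prev = dh_prev + drh * r

        da_z = dz * z * (1.0 - z)
        da_r = dr * r * (1.0 - r)
        g["Wz"] += x.T @ da_z
        g["Uz"] += h_prev.T @ da_z
        g["bz"] += da_z.sum(axis=0)
        g["Wr"] += x.T @ da_r
        g["Ur"] += h_prev.T @ da_r
        g["br"] += da_r.sum(axis=0)

        dh = dh_prev + da_z @ params["Uz"].T + da_r @ params["Ur"].T
    return g


class Adam:
    """Standard Adam with bias correction and optional global-norm clipping."""

    def __init__(self, params: dict, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7, clip_norm: float | None = 5.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        if self.clip_norm is not None:
            norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k in params:
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * grads[k]
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * grads[k] ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
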