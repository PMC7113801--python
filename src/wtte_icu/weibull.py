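"""Weibull distribution primitives and the censoring-aware objective.

The survival model underlying the whole package: remaining time until
cardiac arrest is modelled as Weibull(k, lambda) with shape ``k`` (dimensionless)
and scale ``lam`` (hours), both strictly positive.  Shape < 1 means a failure
rate that decreases with time, shape > 1 an increasing one; the scale locates
the width of the distribution on the time axis.

The training objective is the right-censored negative log-likelihood: an
observed event at remaining time t contributes ``-log f(t)``, a censored
observation contributes ``-log S(t) = (t/lam)**k``.  Everything here is a pure
function, vectorised over NumPy arrays, with scalar inputs returning scalars.

The two link functions map the network's unconstrained head outputs onto the
positive parameter space: softplus for the shape, exp for the scale.
"""

from __future__ import annotations

import math
import warnings
from typing import NamedTuple

import numpy as np

from ._exceptions import ConfigError

__all__ = [
    "WeibullParams",
    "pdf",
    "cdf",
    "survival",
    "nll",
    "nll_grad_raw",
    "link_shape",
    "link_scale",
    "quantile",
    "median_time",
    "PDF_ZERO_SENTINEL",
    "PARAM_FLOOR",
]

# Guard for the k < 1 density singularity at x = 0 and for parameter underflow
# inside the loss (softplus/exp can round to 0 at extreme raw values).
PDF_ZERO_SENTINEL = 1e12
PARAM_FLOOR = 1e-6


class WeibullParams(NamedTuple):
    """Shape ``k`` (> 0, dimensionless) and scale ``lam`` (> 0, hours)."""

    shape: float
    scale: float


def _check_params(shape, scale) -> tuple[np.ndarray, np.ndarray]:
    k = np.asarray(shape, dtype=float)
    lam = np.asarray(scale, dtype=float)
    if np.any(~np.isfinite(k)) or np.any(k <= 0):
        raise ConfigError("shape: must be strictly positive and finite")
    if np.any(~np.isfinite(lam)) or np.any(lam <= 0):
        raise ConfigError("scale: must be strictly positive and finite")
    return k, lam


def _check_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative (hours since the prediction point)")
    return x


def pdf(x, shape, scale):
    """Density f(x) = (k/lam) (x/lam)^(k-1) exp(-(x/lam)^k), per hour.

    At x = 0 the analytic boundary value is returned: k/lam for k = 1, 0 for
    k > 1; for k < 1 the density diverges and a large finite sentinel is
    substituted with a warning.
    """
    x = _check_x(x)
    k, lam = _check_params(shape, scale)
    x, k, lam = np.broadcast_arrays(x, k, lam)
    out = np.empty(x.shape, dtype=float)
    pos = x > 0
    with np.errstate(divide="ignore", over="ignore"):
        xs = x[pos] / lam[pos]
        log_f = (
            np.log(k[pos] / lam[pos]) + (k[pos] - 1.0) * np.log(xs) - xs ** k[pos]
        )
        out[pos] = np.exp(log_f)
    zero = ~pos
    if np.any(zero):
        kz = k[zero]
        vals = np.where(kz > 1.0, 0.0, np.where(kz == 1.0, 1.0 / lam[zero], np.nan))
        if np.any(np.isnan(vals)):
            warnings.warn(
                "Weibull pdf diverges at x=0 for shape < 1; returning a finite sentinel",
                RuntimeWarning,
                stacklevel=2,
            )
            vals = np.where(np.isnan(vals), PDF_ZERO_SENTINEL, vals)
        out[zero] = vals
    return out if out.ndim else float(out)


def cdf(x, shape, scale):
    """P(T <= x) = 1 - exp(-(x/lam)^k); non-decreasing, cdf(0) = 0."""
    x = _check_x(x)
    k, lam = _check_params(shape, scale)
    out = -np.expm1(-((x / lam) ** k))
    return out if np.ndim(out) else float(out)


def survival(x, shape, scale):
    """P(T > x) = exp(-(x/lam)^k)."""
    x = _check_x(x)
    k, lam = _check_params(shape, scale)
    out = np.exp(-((x / lam) ** k))
    return out if np.ndim(out) else float(out)


def nll(t, u, shape, scale):
    """Right-censored negative log-likelihood of one observation.

    Event (u = 1): -log f(t).  Censored (u = 0): -log S(t) = (t/lam)^k.
    Computed in log space; finite for all admissible inputs.

    Parameters
    ----------
    t : remaining time, hours, strictly positive.
    u : event indicator, 1 = cardiac arrest observed, 0 = censored.
    """
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(t <= 0) or np.any(~np.isfinite(t)):
        raise ValueError("remaining time t must be strictly positive and finite")
    k, lam = _check_params(shape, scale)
    log_t, log_lam = np.log(t), np.log(lam)
    log_e = k * (log_t - log_lam)          # log (t/lam)^k
    e = np.exp(log_e)
    # log f(t) = log k - log lam + (k-1)(log t - log lam) - e
    log_f = np.log(k) - log_lam + (k - 1.0) * (log_t - log_lam) - e
    out = np.where(u > 0, -log_f, e)
    return out if out.ndim else float(out)


def nll_grad_raw(t, u, raw_shape, raw_scale):
    """Gradient of ``nll`` w.r.t. the pre-link head outputs, plus the loss.

    The network emits unconstrained reals (raw_shape, raw_scale); the loss is
    nll(t, u, softplus(raw_shape), exp(raw_scale)) with both parameters floored
    at PARAM_FLOOR.  Returns (loss, d/draw_shape, d/draw_scale), all arrays
    broadcast to a common shape.  Used by the training loop; checked against
    central finite differences in the test suite.
    """
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    raw_shape = np.asarray(raw_shape, dtype=float)
    raw_scale = np.asarray(raw_scale, dtype=float)

    k = link_shape(raw_shape)
    lam = link_scale(raw_scale)
    floored_k = k < PARAM_FLOOR
    floored_lam = lam < PARAM_FLOOR
    k = np.maximum(k, PARAM_FLOOR)
    lam = np.maximum(lam, PARAM_FLOOR)

    log_t, log_lam = np.log(t), np.log(lam)
    z = log_t - log_lam
    e = np.exp(np.minimum(k * z, 500.0))   # (t/lam)^k, overflow-guarded
    loss = np.where(u > 0, -(np.log(k) - log_lam + (k - 1.0) * z - e), e)

    # dL/dk = -u/k + (e - u) z ;  dL/dlam = (u - e) k / lam
    dL_dk = -u / k + (e - u) * z
    dL_dlam = (u - e) * k / lam

    dk_draw = _sigmoid(raw_shape)          # d softplus / d raw
    dlam_draw = lam                        # d exp / d raw (at floored lam the exp deriv is lam anyway tiny)
    dk_draw = np.where(floored_k, 0.0, dk_draw)
    dlam_draw = np.where(floored_lam, 0.0, dlam_draw)
    return loss, dL_dk * dk_draw, dL_dlam * dlam_draw


def _sigmoid(x):
    out = np.empty_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def link_shape(raw):
    """Softplus link for the shape head: log(1 + e^raw), strictly positive."""
    raw = np.asarray(raw, dtype=float)
    # stable softplus: max(raw, 0) + log1p(exp(-|raw|))
    out = np.maximum(raw, 0.0) + np.log1p(np.exp(-np.abs(raw)))
    return out if out.ndim else float(out)


def link_scale(raw):
    """Exponential link for the scale head: e^raw, strictly positive."""
    raw = np.asarray(raw, dtype=float)
    out = np.exp(raw)
    return out if out.ndim else float(out)


def quantile(p, shape, scale):
    """Inverse CDF: lam * (-log(1-p))^(1/k), hours."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly inside (0, 1)")
    k, lam = _check_params(shape, scale)
    out = lam * (-np.log1p(-p)) ** (1.0 / k)
    return out if np.ndim(out) else float(out)


def median_time(shape, scale):
    """Median of the distribution, lam * (ln 2)^(1/k) hours.

    Used as the point prediction of remaining time until arrest.
    """
    k, lam = _check_params(shape, scale)
    out = lam * math.log(2) ** (1.0 / k)
    return out if np.ndim(out) else float(out)
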