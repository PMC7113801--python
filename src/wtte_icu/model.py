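"""The recurrent Weibull time-to-event estimator and its cross-validation protocol.

:class:`WeibullGRURegressor` is a scikit-learn style estimator: ``fit`` takes
the windowed covariate tensor plus (remaining_time, event) labels and
minimises the censoring-aware Weibull negative log-likelihood with Adam;
``predict`` returns one (shape, scale) pair per observation, read at the last
unmasked time step.  Defaults follow the published architecture: 50 GRU
units, a 20-unit tanh dense layer, softplus/exponential parameter heads.

Cross-validation is patient-level and stratified by event status: no
patient's observations straddle folds, and standardisation statistics are
refit on each training fold so nothing leaks into validation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from . import _gru, weibull
from ._exceptions import ConfigError, DataError, NumericError
from .preprocess import LabeledWindowSet, WindowStandardizer

__all__ = ["ModelConfig", "WeibullGRURegressor", "train", "kfold_split", "run_cv",
           "save_model", "load_model"]


@dataclass
class ModelConfig:
    """Training-protocol knobs; defaults are the published architecture."""

    gru_units: int = 50
    dense_units: int = 20
    hidden_activation: str = "tanh"
    optimizer: str = "adam"
    learning_rate: float = 0.01
    epochs: int = 300          # paper protocol: 1000; desk-scale default 300
    batch_size: int = 256
    seed: int = 0
    n_folds: int = 5
    clip_norm: float = 5.0
    restore_best: bool = True
    dtype: str = "float64"

    def validate(self) -> "ModelConfig":
        for name in ("gru_units", "dense_units", "batch_size", "n_folds"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be >= 1")
        if self.epochs < 0:
            raise ConfigError("epochs: must be >= 0")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate: must be > 0")
        if self.hidden_activation != "tanh":
            raise ConfigError("hidden_activation: only 'tanh' is supported")
        if self.optimizer.lower() != "adam":
            raise ConfigError("optimizer: only 'adam' is supported")
        return self

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


def _as_labels(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise DataError("y must be (n_observations, 2): [remaining_time, event indicator]")
    t, u = y[:, 0], y[:, 1]
    if np.any(t <= 0):
        raise DataError("remaining_time labels must be strictly positive")
    if not np.all(np.isin(u, (0.0, 1.0))):
        raise DataError("event indicator must be 0 or 1")
    return t, u


def _marginal_raw_fit(t: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Pre-link (raw) parameters of the covariate-free censored Weibull fit."""
    from scipy.optimize import minimize

    def f(raw):
        loss, gs, gl = weibull.nll_grad_raw(t, u, raw[0], raw[1])
        return float(loss.mean()), np.array([gs.mean(), gl.mean()])

    x0 = np.array([np.log(np.expm1(1.0)), float(np.log(t.mean()))])
    res = minimize(f, x0, jac=True, method="L-BFGS-B")
    return res.x if res.success or np.isfinite(res.fun) else x0


class WeibullGRURegressor(BaseEstimator):
    """Masked GRU mapping clinical window tensors to Weibull (shape, scale).

    Parameters mirror :class:`ModelConfig`.  ``fit`` expects
    ``X`` of shape (n_observations, horizon_steps, n_vars) — NaN cells are
    treated as missing (replaced by 0 = the standardized mean), and a step
    whose entire variable vector is NaN is masked so it does not alter the
    recurrent state.  An explicit boolean ``mask`` (True = skip step) can be
    passed instead.

    Fitted attributes
    -----------------
    params_ : dict of weight arrays.
    history_ : DataFrame (epoch, train_cost, val_cost) of per-epoch mean
        negative log-likelihood.
    n_features_in_, n_steps_ : input geometry.
    """

    def __init__(self, gru_units: int = 50, dense_units: int = 20,
                 learning_rate: float = 0.01, epochs: int = 300, batch_size: int = 256,
                 clip_norm: float = 5.0, restore_best: bool = True, shuffle: bool = True,
                 dtype: str = "float64", random_state: int = 0):
        self.gru_units = gru_units
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.clip_norm = clip_norm
        self.restore_best = restore_best
        self.shuffle = shuffle
        self.dtype = dtype
        self.random_state = random_state

    @classmethod
    def from_config(cls, config: ModelConfig, **kw) -> "WeibullGRURegressor":
        config.validate()
        return cls(gru_units=config.gru_units, dense_units=config.dense_units,
                   learning_rate=config.learning_rate, epochs=config.epochs,
                   batch_size=config.batch_size, clip_norm=config.clip_norm,
                   restore_best=config.restore_best, dtype=config.dtype,
                   random_state=config.seed, **kw)

    # -- input handling -------------------------------------------------
    def _prepare(self, X, mask, fitted: bool):
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3:
            raise DataError("X must be 3-D: (observations, steps, variables)")
        if fitted and X.shape[2] != self.n_features_in_:
            raise ConfigError(
                f"n_vars mismatch: model built for {self.n_features_in_} variables, "
                f"got {X.shape[2]}"
            )
        nan_step = np.isnan(X).all(axis=2)
        if mask is None:
            mask = nan_step
        else:
            mask = np.asarray(mask, dtype=bool) | nan_step
        if mask.shape != X.shape[:2]:
            raise DataError("mask must have shape (observations, steps)")
        if mask.all(axis=1).any():
            raise DataError(
                "observation(s) with every step masked: the model cannot emit "
                "parameters from pure padding"
            )
        X = np.where(np.isnan(X), 0.0, X)
        step_ok = (~mask).astype(X.dtype)
        return X, step_ok

    def _num_params(self) -> int:
        return _gru.param_count(self.n_features_in_, self.gru_units, self.dense_units)

    # -- training --------------------------------------------------------
    def fit(self, X, y, mask=None, validation_data=None):
        """Minimise the mean censored Weibull NLL with Adam.

        ``validation_data`` is an optional (X_val, y_val) or
        (X_val, y_val, mask_val) tuple; when given, the per-epoch validation
        cost is recorded and (with ``restore_best``) the weights from the
        best-validation epoch are kept.
        """
        rng = np.random.default_rng(self.random_state)
        t, u = _as_labels(y)
        self.n_features_in_ = np.asarray(X).shape[2]
        self.n_steps_ = np.asarray(X).shape[1]
        X, step_ok = self._prepare(X, mask, fitted=True)
        if len(t) != X.shape[0]:
            raise DataError("X and y disagree on the number of observations")

        val = None
        if validation_data is not None:
            Xv, yv, *mv = validation_data
            tv, uv = _as_labels(yv)
            Xv, step_ok_v = self._prepare(Xv, mv[0] if mv else None, fitted=True)
            val = (Xv, step_ok_v, tv, uv)

        dt = np.dtype(self.dtype)
        params = _gru.init_params(self.n_features_in_, self.gru_units, self.dense_units,
                                  rng, dtype=dt)
        # head biases start at the marginal censored-Weibull fit of the labels,
        # so the network begins at the best covariate-free solution
        raw0 = _marginal_raw_fit(t, u)
        params["bo"][0] = raw0[0]
        params["bo"][1] = raw0[1]
        opt = _gru.Adam(params, lr=self.learning_rate, clip_norm=self.clip_norm)

        n = X.shape[0]
        history = []
        best_cost, best_params = np.inf, None
        if val is not None and self.epochs > 0:
            best_cost = self._cost(params, *val)
            best_params = {k: v.copy() for k, v in params.items()}
        bad_epochs = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            batch_costs, batch_sizes = [], []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                raw, cache = _gru.forward(params, X[idx], step_ok[idx], keep_cache=True)
                loss, g_rs, g_rl = weibull.nll_grad_raw(t[idx], u[idx], raw[:, 0], raw[:, 1])
                cost = float(loss.mean())
                draw = np.stack([g_rs, g_rl], axis=1).astype(dt) / len(idx)
                grads = _gru.backward(params, X[idx], step_ok[idx], cache, draw)
                opt.step(params, grads)
                batch_costs.append(cost)
                batch_sizes.append(len(idx))
            train_cost = float(np.average(batch_costs, weights=batch_sizes))

            val_cost = np.nan
            if val is not None:
                val_cost = self._cost(params, *val)
            history.append((epoch, train_cost, val_cost))

            monitor = val_cost if val is not None else train_cost
            if np.isfinite(monitor) and monitor < best_cost:
                best_cost = monitor
                best_params = {k: v.copy() for k, v in params.items()}
            if not np.isfinite(train_cost):
                bad_epochs += 1
                if bad_epochs >= 3:
                    self.params_ = params
                    raise NumericError(
                        f"non-finite training cost for 3 consecutive epochs "
                        f"(last epoch {epoch}, cost {train_cost})"
                    )
            else:
                bad_epochs = 0

        if self.restore_best and best_params is not None:
            params = best_params
        self.params_ = params
        self.history_ = pd.DataFrame(history, columns=["epoch", "train_cost", "val_cost"])
        return self

    def _cost(self, params, X, step_ok, t, u, batch: int = 4096) -> float:
        total, n = 0.0, X.shape[0]
        for start in range(0, n, batch):
            sl = slice(start, start + batch)
            raw, _ = _gru.forward(params, X[sl], step_ok[sl])
            loss = weibull.nll(t[sl], u[sl],
                               np.maximum(weibull.link_shape(raw[:, 0]), weibull.PARAM_FLOOR),
                               np.maximum(weibull.link_scale(raw[:, 1]), weibull.PARAM_FLOOR))
            total += float(loss.sum())
        return total / n

    # -- inference -------------------------------------------------------
    def predict(self, X, mask=None) -> np.ndarray:
        """Per-observation Weibull parameters, columns (shape, scale)."""
        if not hasattr(self, "params_"):
            raise DataError("model is not fitted")
        X, step_ok = self._prepare(X, mask, fitted=True)
        out = np.empty((X.shape[0], 2))
        for start in range(0, X.shape[0], 4096):
            sl = slice(start, start + 4096)
            raw, _ = _gru.forward(self.params_, X[sl], step_ok[sl])
            out[sl, 0] = np.maximum(weibull.link_shape(raw[:, 0]), weibull.PARAM_FLOOR)
            out[sl, 1] = np.maximum(weibull.link_scale(raw[:, 1]), weibull.PARAM_FLOOR)
        return out

    def predict_risk(self, X, horizon: float, mask=None) -> np.ndarray:
        """P(event within ``horizon`` hours) for each observation."""
        if horizon <= 0:
            raise ValueError("horizon must be > 0")
        p = self.predict(X, mask=mask)
        return weibull.cdf(horizon, p[:, 0], p[:, 1])

    def score(self, X, y, mask=None) -> float:
        """Negative mean NLL (higher is better), sklearn-convention."""
        t, u = _as_labels(y)
        X, step_ok = self._prepare(X, mask, fitted=True)
        return -self._cost(self.params_, X, step_ok, t, u)


def train(window_set: LabeledWindowSet, config: ModelConfig,
          validation: LabeledWindowSet | None = None) -> WeibullGRURegressor:
    """Convenience wrapper: fit an estimator on a labelled window set."""
    config.validate()
    est = WeibullGRURegressor.from_config(config)
    y = window_set.labels[["remaining_time", "u"]].to_numpy(float)
    val = None
    if validation is not None:
        val = (validation.values, validation.labels[["remaining_time", "u"]].to_numpy(float),
               validation.mask)
    return est.fit(window_set.values, y, mask=window_set.mask, validation_data=val)


def kfold_split(patients: pd.DataFrame, n_folds: int = 5, seed: int = 0) -> pd.DataFrame:
    """Patient-level stratified fold assignment (fold index 1..n_folds).

    Stratification is by event indicator, so each validation fold carries its
    share of the rare arrest patients; the partition is disjoint and
    exhaustive at the patient level.
    """
    if n_folds < 2:
        raise ConfigError("n_folds: must be >= 2")
    events = patients["event"].to_numpy(int)
    if events.sum() < n_folds:
        raise DataError(
            f"only {int(events.sum())} event patients for {n_folds} folds; "
            "stratified patient-level split impossible"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold = np.empty(len(patients), dtype=int)
    for i, (_, val_idx) in enumerate(skf.split(np.zeros(len(patients)), events), start=1):
        fold[val_idx] = i
    return pd.DataFrame({"patient_id": patients["patient_id"].astype(str), "fold": fold})


def run_cv(window_set: LabeledWindowSet, patients: pd.DataFrame, config: ModelConfig):
    """Patient-level k-fold cross-validation of the full protocol.

    For each fold: z-score with statistics of the training-fold observations
    only, train a fresh network (validation cost monitored on the held-out
    fold), and predict Weibull parameters for every validation observation.
    Every observation is predicted exactly once; the pooled prediction table
    feeds the horizon-indexed ROC analysis.

    Returns (models, pooled_predictions, fold_assignment, scalers).
    """
    config.validate()
    present = set(window_set.labels["patient_id"].astype(str))
    pts = patients[patients["patient_id"].astype(str).isin(present)].reset_index(drop=True)
    folds = kfold_split(pts, n_folds=config.n_folds, seed=config.seed)
    fold_of = dict(zip(folds["patient_id"], folds["fold"]))
    obs_fold = window_set.labels["patient_id"].astype(str).map(fold_of).to_numpy()

    models, scalers, pooled = [], [], []
    for k in range(1, config.n_folds + 1):
        val_idx = np.where(obs_fold == k)[0]
        train_idx = np.where(obs_fold != k)[0]
        train_set = window_set.subset(train_idx)
        val_set = window_set.subset(val_idx)

        scaler = WindowStandardizer().fit(train_set.values)
        Xt = scaler.transform(train_set.values)
        Xv = scaler.transform(val_set.values)

        fold_config = config.replace(seed=config.seed + k)
        est = WeibullGRURegressor.from_config(fold_config)
        try:
            est.fit(Xt, train_set.labels[["remaining_time", "u"]].to_numpy(float),
                    mask=train_set.mask,
                    validation_data=(Xv, val_set.labels[["remaining_time", "u"]].to_numpy(float),
                                     val_set.mask))
            pred = est.predict(Xv, mask=val_set.mask)
        except (DataError, NumericError) as err:
            raise type(err)(f"fold {k}: {err}") from err
        out = val_set.labels.copy()
        out["fold"] = k
        out["shape"] = pred[:, 0]
        out["scale"] = pred[:, 1]
        pooled.append(out)
        models.append(est)
        scalers.append(scaler)

    pooled_df = pd.concat(pooled, ignore_index=True)
    if len(pooled_df) != window_set.n_observations:
        raise DataError("pooled validation predictions do not cover every observation once")
    return models, pooled_df, folds, scalers


def save_model(est: WeibullGRURegressor, scaler: WindowStandardizer | None, out_dir) -> dict:
    """Weights as .npz plus a portable JSON sidecar (architecture + scaling)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    npz = out_dir / "model_weights.npz"
    np.savez(npz, **est.params_)
    sidecar = {
        "architecture": {
            "gru_units": est.gru_units, "dense_units": est.dense_units,
            "n_vars": int(est.n_features_in_), "horizon_steps": int(est.n_steps_),
            "hidden_activation": "tanh", "heads": ["softplus", "exp"],
            "n_parameters": est._num_params(),
        },
        "config": {k: v for k, v in est.get_params().items()},
        "standardization": None if scaler is None else {
            "mean": scaler.mean_.tolist(), "scale": scaler.scale_.tolist(),
        },
    }
    side = out_dir / "model.json"
    side.write_text(json.dumps(sidecar, indent=2))
    return {"weights": npz, "sidecar": side}


def load_model(in_dir) -> tuple[WeibullGRURegressor, WindowStandardizer | None]:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "model.json").read_text())
    est = WeibullGRURegressor(**{k: v for k, v in sidecar["config"].items()})
    with np.load(in_dir / "model_weights.npz") as z:
        est.params_ = {k: z[k] for k in z.files}
    est.n_features_in_ = sidecar["architecture"]["n_vars"]
    est.n_steps_ = sidecar["architecture"]["horizon_steps"]
    est.history_ = pd.DataFrame(columns=["epoch", "train_cost", "val_cost"])
    scaler = None
    if sidecar["standardization"] is not None:
        scaler = WindowStandardizer()
        scaler.mean_ = np.asarray(sidecar["standardization"]["mean"])
        scaler.scale_ = np.asarray(sidecar["standardization"]["scale"])
        scaler.n_features_in_ = len(scaler.mean_)
    return est, scaler
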