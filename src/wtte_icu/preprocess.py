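"""From long-format clinical series to the masked, labelled window tensor.

The flow mirrors the preprocessing of the source cohort: select the common
variable set, forward-fill daily labs onto the hourly grid, exclude patients
with too much missingness (P_id: per-patient missing-cell count, threshold
1000; P_ir: missing-cell ratio, threshold 20%), then slice every retained
patient's history into overlapping right-aligned windows of up to 48 hourly
steps.  Each window ("observation") is labelled with the remaining time to
the event or to censoring, the latter capped at the safety threshold tau =
72 h, plus the event indicator u.

Within a window, a partially missing hourly vector is completed by
last-observation-carried-forward using only hours inside that window; a step
is masked (skipped by the model) only when all variables are absent at that
step.  Standardisation is z-scoring fitted on training-fold observations
only, so no information leaks across cross-validation folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._exceptions import ConfigError, DataError

__all__ = [
    "DEFAULT_P_ID_MAX",
    "DEFAULT_P_IR_MAX",
    "DEFAULT_TAU",
    "DEFAULT_HORIZON_STEPS",
    "LabeledWindowSet",
    "select_common_features",
    "resample_daily_to_hourly",
    "compute_missingness",
    "filter_patients",
    "cap_censored_tte",
    "build_windows",
    "WindowStandardizer",
    "standardize",
]

logger = logging.getLogger(__name__)

DEFAULT_P_ID_MAX = 1000     # max missing observations per patient
DEFAULT_P_IR_MAX = 0.20     # max missing-observation ratio per patient
DEFAULT_TAU = 72.0          # hours; cap on censored remaining times
DEFAULT_HORIZON_STEPS = 48  # window length, hours


@dataclass
class LabeledWindowSet:
    """The model's input/label contract.

    values : float array (observations, horizon_steps, n_vars); NaN marks a
        still-missing cell after within-window carry-forward.
    mask : bool array (observations, horizon_steps); True where the whole
        step vector is missing (left padding or an empty hour) and the model
        must skip the step.
    labels : DataFrame with one row per observation: obs_id, patient_id,
        prediction_hour, remaining_time (hours), u (event indicator).
    var_names : the variable order of the last axis.
    """

    values: np.ndarray
    mask: np.ndarray
    labels: pd.DataFrame
    var_names: list = field(default_factory=list)

    def __post_init__(self):
        O, T, V = self.values.shape
        if self.mask.shape != (O, T):
            raise DataError("mask shape must be (observations, horizon_steps)")
        if len(self.labels) != O:
            raise DataError("labels must have one row per observation")

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    def subset(self, idx) -> "LabeledWindowSet":
        idx = np.asarray(idx)
        return LabeledWindowSet(
            self.values[idx],
            self.mask[idx],
            self.labels.iloc[idx].reset_index(drop=True),
            list(self.var_names),
        )

    def save(self, out_dir) -> dict:
        """Binary array container plus a labels.csv sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        npz = out_dir / "windows.npz"
        np.savez_compressed(
            npz, values=self.values, mask=self.mask, var_names=np.array(self.var_names)
        )
        labels = out_dir / "labels.csv"
        self.labels.to_csv(labels, index=False)
        return {"windows": npz, "labels": labels}

    @classmethod
    def load(cls, in_dir) -> "LabeledWindowSet":
        in_dir = Path(in_dir)
        with np.load(in_dir / "windows.npz", allow_pickle=False) as z:
            values, mask = z["values"], z["mask"]
            var_names = [str(v) for v in z["var_names"]]
        labels = pd.read_csv(in_dir / "labels.csv")
        return cls(values, mask, labels, var_names)


def select_common_features(series: pd.DataFrame, required_vars, patients: pd.DataFrame | None = None):
    """Pivot the long series to a per-(patient, hour) wide table.

    Restricted to ``required_vars``; the hour grid of each patient runs from 0
    to the hour before their outcome (when ``patients`` is given) or to their
    last observed hour.  Patients missing a required variable entirely are
    flagged, not dropped.

    Returns (wide_table, flagged) where ``flagged`` maps patient_id to the
    list of entirely-absent variables.
    """
    required_vars = list(required_vars)
    if not required_vars:
        raise ConfigError("required_vars: must name at least one variable")
    sub = series[series["variable"].isin(required_vars)]
    wide = sub.pivot_table(
        index=["patient_id", "hour"], columns="variable", values="value", aggfunc="last"
    )
    wide = wide.reindex(columns=required_vars)
    wide.columns.name = None

    # full per-patient hourly grid
    if patients is not None:
        last_hour = {
            str(r.patient_id): max(int(np.ceil(r.outcome_time)) - 1, 0)
            for r in patients.itertuples()
        }
    else:
        last_hour = sub.groupby("patient_id")["hour"].max().to_dict()
    idx = pd.MultiIndex.from_tuples(
        [(pid, h) for pid, lh in last_hour.items() for h in range(int(lh) + 1)],
        names=["patient_id", "hour"],
    )
    wide = wide.reindex(idx)

    flagged = {}
    present = sub.groupby("patient_id")["variable"].agg(set)
    for pid in last_hour:
        missing = [v for v in required_vars if v not in present.get(pid, set())]
        if missing:
            flagged[pid] = missing
            logger.warning("patient %s: variables never observed: %s", pid, missing)
    return wide, flagged


def resample_daily_to_hourly(table: pd.DataFrame, daily_vars, limit: int = 23) -> pd.DataFrame:
    """Forward-fill daily variables onto the hourly grid, per patient.

    ``limit`` bounds the carry distance (23 h bridges one daily cadence).
    """
    daily_vars = [v for v in daily_vars if v in table.columns]
    if not daily_vars:
        return table.copy()
    out = table.copy()
    filled = out.groupby(level="patient_id", sort=False)[daily_vars].ffill(limit=limit)
    out[daily_vars] = filled
    return out


def compute_missingness(table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient P_id (missing-cell count) and P_ir (missing-cell ratio).

    The denominator of P_ir is the patient's full (hours x variables) grid.
    """
    if table.empty:
        raise DataError("feature table is empty")
    miss = table.isna().groupby(level="patient_id", sort=False).sum().sum(axis=1)
    hours = table.groupby(level="patient_id", sort=False).size()
    total = hours * table.shape[1]
    if (total == 0).any():
        bad = total.index[total == 0][0]
        raise DataError(f"patient {bad}: zero observation rows")
    stats = pd.DataFrame(
        {"patient_id": miss.index, "p_id": miss.to_numpy(int), "p_ir": (miss / total).to_numpy()}
    ).reset_index(drop=True)
    return stats


def filter_patients(stats: pd.DataFrame, p_id_max: float = DEFAULT_P_ID_MAX,
                    p_ir_max: float = DEFAULT_P_IR_MAX) -> list:
    """Retain patients with P_id <= p_id_max and P_ir <= p_ir_max."""
    retained = []
    for r in stats.itertuples():
        if r.p_id > p_id_max:
            logger.info("excluding %s: p_id=%d > %g", r.patient_id, r.p_id, p_id_max)
        elif r.p_ir > p_ir_max:
            logger.info("excluding %s: p_ir=%.3f > %g", r.patient_id, r.p_ir, p_ir_max)
        else:
            retained.append(r.patient_id)
    if not retained:
        warnings.warn("missingness filter excluded every patient", UserWarning, stacklevel=2)
    return retained


def cap_censored_tte(remaining_time, u, tau: float = DEFAULT_TAU):
    """Cap censored remaining times at tau; event times pass through."""
    if tau <= 0:
        raise ConfigError("tau: must be > 0")
    remaining_time = np.asarray(remaining_time, dtype=float)
    u = np.asarray(u)
    out = np.where(u > 0, remaining_time, np.minimum(remaining_time, tau))
    return out if out.ndim else float(out)


def _locf_index(observed: np.ndarray) -> np.ndarray:
    """For each (hour, var) cell, the most recent hour with an observation (-1 if none)."""
    H, V = observed.shape
    idx = np.where(observed, np.arange(H)[:, None], -1)
    return np.maximum.accumulate(idx, axis=0)


def build_windows(table: pd.DataFrame, patients: pd.DataFrame,
                  horizon_steps: int = DEFAULT_HORIZON_STEPS, tau: float = DEFAULT_TAU,
                  max_windows: int | None = None, window_selection: str = "last",
                  dtype=np.float32) -> LabeledWindowSet:
    """Slice each patient's hourly history into overlapping labelled windows.

    For each eligible prediction hour t, one observation holds the most recent
    ``min(t+1, horizon_steps)`` hourly vectors right-aligned, left-padded with
    masked steps.  Eligible t: remaining time >= 1 h for event patients
    (the inclusion rule), t strictly before the censoring time otherwise; each
    patient contributes at most ``max_windows`` (default ``horizon_steps``)
    windows, the latest ones by default.

    Labels: remaining_time = outcome_time - t, capped at tau when censored.
    """
    if horizon_steps < 1:
        raise ConfigError("horizon_steps: must be >= 1")
    if tau <= 0:
        raise ConfigError("tau: must be > 0")
    if window_selection not in ("last", "first"):
        raise ConfigError("window_selection: must be 'last' or 'first'")
    if max_windows is None:
        max_windows = horizon_steps

    var_names = list(table.columns)
    V = len(var_names)
    T = horizon_steps
    chunks_vals, chunks_mask, label_rows = [], [], []

    grouped = dict(tuple(table.groupby(level="patient_id", sort=False)))
    for prow in patients.itertuples():
        pid = str(prow.patient_id)
        if pid not in grouped:
            continue
        sub = grouped[pid].droplevel("patient_id")
        H = int(sub.index.max()) + 1
        grid = np.full((H, V), np.nan)
        grid[sub.index.to_numpy(int)] = sub.to_numpy(float)
        observed = ~np.isnan(grid)
        li = _locf_index(observed)

        outcome = float(prow.outcome_time)
        u = int(prow.event)
        if u:
            t_max = int(np.floor(outcome - 1.0))    # remaining >= 1 h
            if outcome <= 1.0:
                warnings.warn(
                    f"patient {pid}: event within the first hour, no eligible window",
                    UserWarning, stacklevel=2,
                )
                continue
        else:
            t_max = int(np.ceil(outcome)) - 1       # t strictly before censoring
        t_max = min(t_max, H - 1)
        if t_max < 0:
            continue
        t_all = np.arange(0, t_max + 1)
        if len(t_all) > max_windows:
            t_all = t_all[-max_windows:] if window_selection == "last" else t_all[:max_windows]

        W = len(t_all)
        steps = t_all[:, None] - (T - 1 - np.arange(T))[None, :]   # (W, T) hour index per step
        pad = steps < 0
        win_start = np.maximum(t_all - T + 1, 0)
        src = li[steps.clip(min=0)]                                # (W, T, V)
        valid = (~pad[:, :, None]) & (src >= win_start[:, None, None]) & (src >= 0)
        vals = np.where(valid, grid[src.clip(min=0), np.arange(V)[None, None, :]], np.nan)
        step_mask = pad | (~valid).all(axis=2)

        keep = ~step_mask.all(axis=1)
        if not keep.all():
            warnings.warn(
                f"patient {pid}: {int((~keep).sum())} fully-missing window(s) dropped",
                UserWarning, stacklevel=2,
            )
        vals, step_mask, t_kept = vals[keep], step_mask[keep], t_all[keep]

        remaining = outcome - t_kept
        remaining = cap_censored_tte(remaining, np.full_like(t_kept, u), tau)
        chunks_vals.append(vals.astype(dtype))
        chunks_mask.append(step_mask)
        label_rows.extend(
            {"patient_id": pid, "prediction_hour": int(t), "remaining_time": float(r), "u": u}
            for t, r in zip(t_kept, np.atleast_1d(remaining))
        )

    if not chunks_vals:
        values = np.empty((0, T, V), dtype=dtype)
        mask = np.empty((0, T), dtype=bool)
    else:
        values = np.concatenate(chunks_vals, axis=0)
        mask = np.concatenate(chunks_mask, axis=0)
    labels = pd.DataFrame(label_rows, columns=["patient_id", "prediction_hour", "remaining_time", "u"])
    labels.insert(0, "obs_id", np.arange(len(labels)))
    return LabeledWindowSet(values, mask, labels, var_names)


class WindowStandardizer(TransformerMixin, BaseEstimator):
    """Per-variable z-scoring over the unmasked, observed cells of a window set.

    Fit on training-fold observations only; the stored mean_/scale_ are reused
    on validation folds.  NaN cells (missing) and masked steps pass through
    unchanged; a zero-variance variable is centred but scaled by 1, with a
    warning.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise DataError("X must be a 3-D (observations, steps, variables) array")
        flat = X.reshape(-1, X.shape[2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.mean_ = np.nanmean(flat, axis=0)
            sd = np.nanstd(flat, axis=0)
        self.mean_ = np.where(np.isnan(self.mean_), 0.0, self.mean_)
        zero = ~(sd > 0)
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance variable(s); scaling by 1",
                UserWarning, stacklevel=2,
            )
        self.scale_ = np.where(zero, 1.0, sd)
        self.n_features_in_ = X.shape[2]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


def standardize(window_set: LabeledWindowSet, stats_source: LabeledWindowSet | None = None):
    """Z-score a window set with statistics from ``stats_source`` (default: itself).

    Returns (standardised window set, fitted WindowStandardizer).
    """
    source = window_set if stats_source is None else stats_source
    scaler = WindowStandardizer().fit(source.values)
    values = scaler.transform(window_set.values).astype(window_set.values.dtype)
    return LabeledWindowSet(values, window_set.mask.copy(), window_set.labels.copy(),
                            list(window_set.var_names)), scaler
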