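"""Horizon-indexed (time-dependent) ROC analysis and risk summaries.

The risk score of an observation at horizon h is the predicted probability
of cardiac arrest within the next h hours, i.e. the Weibull CDF at h
evaluated at the observation's predicted (shape, scale).  At each horizon of
the evaluation grid (default 1, 8, 16, 24, 32, 40, 48 h) the cases are the
event-group observations whose remaining time matches the horizon and the
controls are censored-group observations still under observation at that
horizon; the ROC area is then the midrank Mann-Whitney probability that a
random case outscores a random control, with the operating point chosen by
Youden's J.

Remaining times are real-valued hours; horizon matching bins them to the
nearest integer hour, the resolution of the underlying clinical grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from . import weibull
from ._exceptions import ConfigError, DataError

__all__ = [
    "DEFAULT_HORIZONS",
    "HorizonScoreSet",
    "TaucResult",
    "risk_at_horizon",
    "build_horizon_sets",
    "roc_auc",
    "tauc_table",
    "risk_trajectories",
    "patient_cdf_curves",
]

DEFAULT_HORIZONS = (1, 8, 16, 24, 32, 40, 48)


@dataclass
class HorizonScoreSet:
    """Case/control risk scores at one prediction horizon (hours)."""

    horizon: float
    cases: np.ndarray
    controls: np.ndarray

    @property
    def computable(self) -> bool:
        return len(self.cases) > 0 and len(self.controls) > 0


@dataclass
class TaucResult:
    """AUC and Youden operating point at one horizon."""

    horizon: float
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    n_cases: int
    n_controls: int
    computable: bool = True


def risk_at_horizon(shape, scale, horizon) -> np.ndarray:
    """P(event within ``horizon`` hours) = Weibull CDF at the horizon."""
    horizon = np.asarray(horizon, dtype=float)
    if np.any(horizon <= 0):
        raise ValueError("horizon must be > 0")
    return weibull.cdf(horizon, shape, scale)


def build_horizon_sets(pooled: pd.DataFrame, horizons=DEFAULT_HORIZONS,
                       control_matching: str = "risk_set",
                       score: str = "cdf") -> list[HorizonScoreSet]:
    """Assemble case/control score sets for each horizon.

    ``pooled`` is the cross-validation prediction table (columns
    remaining_time, u, shape, scale).  Cases at horizon h: event observations
    with remaining time h (nearest hour).  Controls: censored observations
    with tau-capped remaining time >= h under the default risk-set
    convention, or exactly h with ``control_matching='exact'``.  The score
    is the CDF at h; ``score='pdf'`` exposes the density reading instead.
    """
    if control_matching not in ("risk_set", "exact"):
        raise ConfigError("control_matching: must be 'risk_set' or 'exact'")
    if score not in ("cdf", "pdf"):
        raise ConfigError("score: must be 'cdf' or 'pdf'")
    need = {"remaining_time", "u", "shape", "scale"}
    if not need.issubset(pooled.columns):
        raise DataError(f"pooled predictions missing columns {sorted(need - set(pooled.columns))}")

    rt = np.round(pooled["remaining_time"].to_numpy(float)).astype(int)
    u = pooled["u"].to_numpy(int)
    k = pooled["shape"].to_numpy(float)
    lam = pooled["scale"].to_numpy(float)

    out = []
    for h in horizons:
        scorer = weibull.cdf if score == "cdf" else weibull.pdf
        case_idx = (u == 1) & (rt == h)
        if control_matching == "risk_set":
            ctrl_idx = (u == 0) & (rt >= h)
        else:
            ctrl_idx = (u == 0) & (rt == h)
        cases = np.asarray(scorer(float(h), k[case_idx], lam[case_idx]), dtype=float)
        controls = np.asarray(scorer(float(h), k[ctrl_idx], lam[ctrl_idx]), dtype=float)
        out.append(HorizonScoreSet(float(h), np.atleast_1d(cases), np.atleast_1d(controls)))
    return out


def roc_auc(score_set: HorizonScoreSet) -> TaucResult:
    """Mann-Whitney AUC (ties at half weight) plus the Youden operating point.

    An empty case or control side yields a flagged, not-computable result
    rather than a silent skip.
    """
    if not score_set.computable:
        return TaucResult(score_set.horizon, np.nan, np.nan, np.nan, np.nan,
                          len(score_set.cases), len(score_set.controls), computable=False)
    y = np.concatenate([np.ones(len(score_set.cases), int),
                        np.zeros(len(score_set.controls), int)])
    s = np.concatenate([score_set.cases, score_set.controls])
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    best = int(np.argmax(j))
    return TaucResult(score_set.horizon, auc, float(tpr[best]), float(1.0 - fpr[best]),
                      float(thr[best]), len(score_set.cases), len(score_set.controls))


def tauc_table(pooled: pd.DataFrame, horizons=DEFAULT_HORIZONS,
               control_matching: str = "risk_set", score: str = "cdf") -> pd.DataFrame:
    """One TaucResult row per horizon of the grid."""
    rows = [roc_auc(s) for s in build_horizon_sets(pooled, horizons, control_matching, score)]
    return pd.DataFrame(
        [(r.horizon, r.auc, r.sensitivity, r.specificity, r.n_cases, r.n_controls, r.computable)
         for r in rows],
        columns=["horizon", "auc", "sensitivity", "specificity",
                 "n_cases", "n_controls", "computable"],
    )


def risk_trajectories(pooled: pd.DataFrame, horizon_for_risk: float = 24.0,
                      max_remaining: int | None = None) -> pd.DataFrame:
    """Group-wise risk distribution as a function of remaining time.

    For each remaining-time point (nearest hour, descending to 1) and each
    group (event / censored), reports the median and interquartile range of
    the risk score P(event within ``horizon_for_risk`` hours).  Drives the
    two-band trajectory plot showing when the groups separate.
    """
    rt = np.round(pooled["remaining_time"].to_numpy(float)).astype(int)
    risk = risk_at_horizon(pooled["shape"].to_numpy(float),
                           pooled["scale"].to_numpy(float), horizon_for_risk)
    df = pd.DataFrame({"remaining": rt, "u": pooled["u"].to_numpy(int), "risk": risk})
    if max_remaining is None:
        max_remaining = int(df["remaining"].max()) if len(df) else 0
    rows = []
    for group, name in ((1, "event"), (0, "censored")):
        sub = df[df["u"] == group]
        for r in range(max_remaining, 0, -1):
            sel = sub.loc[sub["remaining"] == r, "risk"]
            if len(sel):
                q25, q50, q75 = np.percentile(sel, [25, 50, 75])
            else:
                q25 = q50 = q75 = np.nan
            rows.append((name, r, len(sel), q25, q50, q75))
    return pd.DataFrame(rows, columns=["group", "remaining", "n", "q25", "median", "q75"])


def patient_cdf_curves(pooled: pd.DataFrame, patient_id: str,
                       future_grid=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-prediction-hour CDF curves and point remaining-time predictions.

    For each prediction hour of one patient, evaluates the predicted CDF over
    a grid of future hours and reports the predicted remaining time as the
    median of the predicted distribution.  Returns (curves, summary).
    """
    sub = pooled[pooled["patient_id"].astype(str) == str(patient_id)]
    if sub.empty:
        raise DataError(f"patient {patient_id}: no predictions available")
    if future_grid is None:
        future_grid = np.arange(0.0, 48.5, 0.5)
    future_grid = np.asarray(future_grid, dtype=float)

    curve_rows, summary_rows = [], []
    for r in sub.itertuples():
        cdf_vals = weibull.cdf(future_grid, r.shape, r.scale)
        curve_rows.extend(
            (r.prediction_hour, float(x), float(c)) for x, c in zip(future_grid, cdf_vals)
        )
        summary_rows.append(
            (r.prediction_hour, float(r.remaining_time),
             float(weibull.median_time(r.shape, r.scale)), float(r.shape), float(r.scale))
        )
    curves = pd.DataFrame(curve_rows, columns=["prediction_hour", "future_hour", "cdf"])
    summary = pd.DataFrame(
        summary_rows,
        columns=["prediction_hour", "remaining_time", "predicted_remaining", "shape", "scale"],
    )
    return curves, summary


def write_evaluation(out_dir, tauc: pd.DataFrame, trajectories: pd.DataFrame | None = None,
                     curves: dict | None = None) -> dict:
    """Persist tauc.csv, trajectories.csv and per-patient CDF curve files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    p = out_dir / "tauc.csv"
    tauc.to_csv(p, index=False)
    written["tauc"] = p
    if trajectories is not None:
        p = out_dir / "trajectories.csv"
        trajectories.to_csv(p, index=False)
        written["trajectories"] = p
    for pid, df in (curves or {}).items():
        p = out_dir / f"cdf_curves_{pid}.csv"
        df.to_csv(p, index=False)
        written[f"cdf_curves_{pid}"] = p
    return written
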