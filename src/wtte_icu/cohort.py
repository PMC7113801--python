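"""Seeded synthetic ICU cohort generator.

Emulates the statistical structure of a medical-ICU cardiac-arrest cohort:
a small event group and a large censored group, 45 common time-dependent
variables spanning six clinical categories (vitals, organ-failure scores,
labs, demographics, diagnoses, medications), hourly vitals and daily labs,
substantial missingness, and event times whose accelerated-failure-time
hazard depends on a subset of covariates.  Censored stays are capped by the
72 h safety threshold applied downstream.

Event-time model: for an event patient with per-variable severity offsets
``b`` (standard normal), the arrest time is drawn from
Weibull(true_shape, scale = baseline_scale * exp(hazard_weights . b)).
Covariate trajectories of event patients additionally drift toward deranged
values over the final ``drift_window_hours`` before the arrest, so that risk
is learnable from recent history.  Censored stay lengths are log-normal
around a 72 h median, independent of the event mechanism.

Everything is driven by a single seed; the same spec regenerates a
bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, DataError

__all__ = [
    "CohortSpec",
    "PatientRecord",
    "variable_catalog",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
]

_CATEGORY_PLAN = (
    # (category, count per 45 variables, sampling)
    ("vital", 15, "hourly"),
    ("sofa", 5, "daily"),
    ("lab", 10, "daily"),
    ("demo", 5, "static"),
    ("dx", 5, "static"),
    ("med", 5, "hourly"),
)


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the synthetic generator.

    Defaults reproduce the published cohort arithmetic: 37 event + 722
    censored patients, 45 variables, 48 h windows, tau = 72 h.
    """

    n_event: int = 37
    n_censored: int = 722
    n_vars: int = 45
    horizon_steps: int = 48
    tau: float = 72.0
    hazard_weights: tuple = (-0.25,) * 8  # per-variable AFT coefficients on the log-scale
    true_shape: float = 1.5
    baseline_scale: float = 96.0  # hours, at covariate mean
    missing_rate_hourly: float = 0.15
    missing_rate_daily: float = 0.05
    daily_var_fraction: float = 1.0 / 3.0
    drift_window_hours: float = 16.0
    drift_amplitude: float = 3.0
    drift_n_vars: int = 10
    censored_stay_median: float = 72.0
    censored_stay_sigma: float = 0.5  # log-scale SD of the log-normal stay length
    min_outcome_hours: float = 2.0
    max_stay_hours: float = 240.0  # series length cap; outcome times are not capped
    ar_coef: float = 0.8
    noise_sd: float = 0.6
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_event < 1:
            raise ConfigError("n_event: must be >= 1")
        if self.n_censored < 0:
            raise ConfigError("n_censored: must be >= 0")
        if self.n_vars < 1:
            raise ConfigError("n_vars: must be >= 1")
        if self.horizon_steps < 1:
            raise ConfigError("horizon_steps: must be >= 1")
        for name in ("missing_rate_hourly", "missing_rate_daily", "daily_var_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1], got {v}")
        for name in ("true_shape", "baseline_scale", "tau", "censored_stay_median",
                     "min_outcome_hours", "max_stay_hours"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")
        if not np.isscalar(self.hazard_weights) and len(self.hazard_weights) > self.n_vars:
            raise ConfigError("hazard_weights: more coefficients than variables")
        if not 0 <= self.drift_n_vars <= self.n_vars:
            raise ConfigError("drift_n_vars: must lie in [0, n_vars]")
        return self

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class PatientRecord:
    """One patient: covariate time series plus outcome.

    ``series`` maps variable name -> list of (hour, value) pairs on a 0-based
    integer hour grid; ``event`` is 1 when cardiac arrest was observed, 0 when
    the stay ended without it (censored); ``outcome_time`` is hours from the
    series start to the event or to censoring.
    """

    patient_id: str
    series: dict
    static: dict
    event: int
    outcome_time: float

    def validate(self) -> "PatientRecord":
        if self.event not in (0, 1):
            raise DataError(f"{self.patient_id}: event must be 0 or 1")
        if not (self.outcome_time > 0 and math.isfinite(self.outcome_time)):
            raise DataError(f"{self.patient_id}: outcome_time must be positive and finite")
        for var, pairs in self.series.items():
            for h, _ in pairs:
                if not 0 <= h <= self.outcome_time:
                    raise DataError(
                        f"{self.patient_id}: hour {h} of {var} outside [0, outcome_time]"
                    )
        return self


def variable_catalog(n_vars: int) -> pd.DataFrame:
    """Names, categories and sampling cadence of the common variables.

    The 45-variable default is split across six categories; for other counts
    the category proportions are kept approximately.
    """
    rows = []
    total = sum(c for _, c, _ in _CATEGORY_PLAN)
    for cat, count, sampling in _CATEGORY_PLAN:
        k = max(1, round(count * n_vars / total))
        for i in range(k):
            rows.append((f"{cat}_{i:02d}", cat, sampling))
    rows = rows[:n_vars]
    while len(rows) < n_vars:
        i = len(rows)
        rows.append((f"vital_x{i:02d}", "vital", "hourly"))
    return pd.DataFrame(rows, columns=["variable", "category", "sampling"])


def _draw_event_times(rng, spec: CohortSpec, log_scale_shift: np.ndarray) -> np.ndarray:
    """Weibull event times with covariate-dependent scale, floored by rejection."""
    scale = spec.baseline_scale * np.exp(log_scale_shift)
    t = scale * rng.weibull(spec.true_shape, size=scale.shape)
    for _ in range(1000):
        bad = t < spec.min_outcome_hours
        if not bad.any():
            break
        t[bad] = scale[bad] * rng.weibull(spec.true_shape, size=int(bad.sum()))
    t[t < spec.min_outcome_hours] = spec.min_outcome_hours
    return t


def _draw_censored_stays(rng, spec: CohortSpec, n: int) -> np.ndarray:
    mu = math.log(spec.censored_stay_median)
    t = rng.lognormal(mu, spec.censored_stay_sigma, size=n)
    return np.clip(t, spec.min_outcome_hours, None)


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate n_event + n_censored fully observed patient records.

    Missingness is injected separately by :func:`inject_missingness` so that
    tests can reason about the two mechanisms independently.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    catalog = variable_catalog(spec.n_vars)
    var_names = catalog["variable"].to_list()
    static_vars = catalog.loc[catalog["sampling"] == "static", "variable"].to_list()

    w = np.zeros(spec.n_vars)
    if np.isscalar(spec.hazard_weights):
        w[:] = float(spec.hazard_weights)
    else:
        w[: len(spec.hazard_weights)] = np.asarray(spec.hazard_weights, dtype=float)

    n = spec.n_event + spec.n_censored
    # per-patient per-variable severity offsets; the hazard signal
    offsets = rng.standard_normal((n, spec.n_vars))
    log_shift = offsets @ w

    event_times = _draw_event_times(rng, spec, log_shift[: spec.n_event])
    censored_times = _draw_censored_stays(rng, spec, spec.n_censored)
    # the stay cap bounds the outcome itself so the series spans the whole stay
    outcome = np.minimum(np.concatenate([event_times, censored_times]), spec.max_stay_hours)
    events = np.concatenate([np.ones(spec.n_event, int), np.zeros(spec.n_censored, int)])

    records = []
    for i in range(n):
        t_out = float(outcome[i])
        n_hours = max(int(math.ceil(t_out)), 1)
        hours = np.arange(n_hours)
        # AR(1) around the patient's severity offset, vectorised over variables
        eps = rng.standard_normal((n_hours, spec.n_vars)) * spec.noise_sd
        x = np.empty((n_hours, spec.n_vars))
        x[0] = offsets[i] + eps[0]
        for h in range(1, n_hours):
            x[h] = offsets[i] + spec.ar_coef * (x[h - 1] - offsets[i]) + eps[h]
        if events[i] and spec.drift_n_vars and spec.drift_window_hours > 0:
            remaining = t_out - hours
            ramp = np.clip(1.0 - remaining / spec.drift_window_hours, 0.0, 1.0)
            x[:, : spec.drift_n_vars] += spec.drift_amplitude * ramp[:, None]
        series = {
            var_names[v]: [(int(h), float(x[h, v])) for h in hours]
            for v in range(spec.n_vars)
        }
        static = {v: float(offsets[i, var_names.index(v)]) for v in static_vars}
        rec = PatientRecord(
            patient_id=f"p{i:04d}",
            series=series,
            static=static,
            event=int(events[i]),
            outcome_time=t_out,
        )
        records.append(rec.validate())
    return records


def inject_missingness(records: Sequence[PatientRecord], spec: CohortSpec) -> list[PatientRecord]:
    """Thin the fully observed series to the cohort's sampling pattern.

    Daily variables keep values only every 24th hour; remaining cells are
    deleted independently at the configured rates.  The final pre-outcome hour
    of every event patient keeps at least one observed variable, so the
    "observed at least one hour before arrest" inclusion rule stays satisfiable.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 104729)  # decoupled stream
    catalog = variable_catalog(spec.n_vars)
    n_daily = round(spec.daily_var_fraction * spec.n_vars)
    # daily cadence applies to the lab/score block first, by catalog order
    daily_order = catalog.sort_values(
        by="sampling", key=lambda s: s.map({"daily": 0, "static": 1, "hourly": 2})
    )["variable"].to_list()
    daily_vars = set(daily_order[:n_daily])

    out = []
    for rec in records:
        new_series = {}
        for var, pairs in rec.series.items():
            rate = spec.missing_rate_daily if var in daily_vars else spec.missing_rate_hourly
            if var in daily_vars:
                pairs = [p for p in pairs if p[0] % 24 == 0]
            if rate > 0 and pairs:
                keep = rng.random(len(pairs)) >= rate
                pairs = [p for p, k in zip(pairs, keep) if k]
            new_series[var] = list(pairs)
        if rec.event:
            last_hour = max((h for pairs in rec.series.values() for h, _ in pairs), default=0)
            if not any(pairs and pairs[-1][0] == last_hour for pairs in new_series.values()):
                # restore one protected observation at the final pre-outcome hour
                for var, pairs in rec.series.items():
                    orig = [p for p in pairs if p[0] == last_hour]
                    if orig:
                        new_series[var] = sorted(set(new_series[var]) | {orig[0]})
                        break
        out.append(
            PatientRecord(rec.patient_id, new_series, rec.static, rec.event, rec.outcome_time)
        )
    return out


def cohort_frames(records: Sequence[PatientRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format series table and patient-level outcome table."""
    srows = [
        (r.patient_id, h, var, v)
        for r in records
        for var, pairs in r.series.items()
        for h, v in pairs
    ]
    series = pd.DataFrame(srows, columns=["patient_id", "hour", "variable", "value"])
    static_cols = sorted({k for r in records for k in r.static})
    prows = [
        {"patient_id": r.patient_id, "event": r.event, "outcome_time": r.outcome_time,
         **{c: r.static.get(c, np.nan) for c in static_cols}}
        for r in records
    ]
    patients = pd.DataFrame(prows)
    return series, patients


def write_cohort(records: Sequence[PatientRecord], out_dir) -> dict:
    """Write series.csv / patients.csv (UTF-8, header row, '.' decimals)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, patients = cohort_frames(records)
    series_path = out_dir / "series.csv"
    patients_path = out_dir / "patients.csv"
    series.to_csv(series_path, index=False)
    patients.to_csv(patients_path, index=False)
    return {"series": series_path, "patients": patients_path}


def read_cohort(in_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    in_dir = Path(in_dir)
    series = pd.read_csv(in_dir / "series.csv")
    patients = pd.read_csv(in_dir / "patients.csv")
    expected = {"patient_id", "hour", "variable", "value"}
    if not expected.issubset(series.columns):
        raise DataError(f"series.csv: missing columns {sorted(expected - set(series.columns))}")
    if not {"patient_id", "event", "outcome_time"}.issubset(patients.columns):
        raise DataError("patients.csv: requires patient_id, event, outcome_time columns")
    return series, patients
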