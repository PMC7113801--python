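"""End-to-end orchestration: simulate -> preprocess -> cross-validate -> evaluate.

A single :class:`RunConfig` (loadable from YAML) carries every knob of the
four stages; one global seed fans out to per-stage seeds by fixed offsets so
stages are individually reproducible.  ``run_pipeline`` writes every
intermediate artifact plus a manifest with config echo, per-stage row counts
and content digests; the same config and seed reproduce identical digests on
one device.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort, evaluate, model, preprocess
from ._exceptions import ConfigError, DataError

__all__ = ["PrepConfig", "EvalConfig", "RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

# per-stage seed offsets (stage seed = global seed + offset, kept below 2**31)
SEED_OFFSETS = {"cohort": 0, "model": 10_007, "eval": 20_011}


@dataclass
class PrepConfig:
    p_id_max: float = preprocess.DEFAULT_P_ID_MAX
    p_ir_max: float = preprocess.DEFAULT_P_IR_MAX
    tau: float = preprocess.DEFAULT_TAU
    horizon_steps: int = preprocess.DEFAULT_HORIZON_STEPS
    max_windows: int | None = None
    window_selection: str = "last"
    daily_ffill_limit: int = 23

    def validate(self) -> "PrepConfig":
        if self.tau <= 0:
            raise ConfigError("prep.tau: must be > 0")
        if self.horizon_steps < 1:
            raise ConfigError("prep.horizon_steps: must be >= 1")
        if self.p_id_max < 0 or not 0 <= self.p_ir_max <= 1:
            raise ConfigError("prep.p_id_max/p_ir_max: thresholds out of range")
        return self


@dataclass
class EvalConfig:
    horizons: tuple = evaluate.DEFAULT_HORIZONS
    control_matching: str = "risk_set"
    score: str = "cdf"
    horizon_for_risk: float = 24.0
    curve_patients: int = 1  # per group

    def validate(self) -> "EvalConfig":
        if not self.horizons:
            raise ConfigError("eval.horizons: must list at least one horizon")
        if any(h <= 0 for h in self.horizons):
            raise ConfigError("eval.horizons: all horizons must be > 0")
        return self


@dataclass
class RunConfig:
    cohort: cohort.CohortSpec = field(default_factory=cohort.CohortSpec)
    prep: PrepConfig = field(default_factory=PrepConfig)
    model: model.ModelConfig = field(default_factory=model.ModelConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    out_dir: str = "wtte_run"
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.cohort.validate()
        self.prep.validate()
        self.model.validate()
        self.eval.validate()
        return self

    def seeded(self) -> "RunConfig":
        """Fan the global seed out to the stage configs."""
        return dataclasses.replace(
            self,
            cohort=self.cohort.replace(seed=self.seed + SEED_OFFSETS["cohort"]),
            model=self.model.replace(seed=self.seed + SEED_OFFSETS["model"]),
        )


def load_config(path, seed: int | None = None, out_dir=None) -> RunConfig:
    """Build a RunConfig from a YAML mapping with cohort/prep/model/eval sections."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw, seed=seed, out_dir=out_dir)


def config_from_dict(raw: dict, seed: int | None = None, out_dir=None) -> RunConfig:
    def build(cls, section):
        data = dict(raw.get(section) or {})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"{section}: unknown keys {sorted(unknown)}")
        if "hazard_weights" in data and isinstance(data["hazard_weights"], list):
            data["hazard_weights"] = tuple(data["hazard_weights"])
        if "horizons" in data and isinstance(data["horizons"], list):
            data["horizons"] = tuple(data["horizons"])
        return cls(**data)

    cfg = RunConfig(
        cohort=build(cohort.CohortSpec, "cohort"),
        prep=build(PrepConfig, "prep"),
        model=build(model.ModelConfig, "model"),
        eval=build(EvalConfig, "eval"),
        out_dir=str(out_dir if out_dir is not None else raw.get("out_dir", "wtte_run")),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
    )
    return cfg.validate()


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_stage(config: RunConfig, out_dir: Path) -> tuple:
    spec = config.cohort
    records = cohort.generate_cohort(spec)
    if spec.missing_rate_hourly > 0 or spec.missing_rate_daily > 0 or spec.daily_var_fraction > 0:
        records = cohort.inject_missingness(records, spec)
    paths = cohort.write_cohort(records, out_dir)
    logger.info("[simulate] %d patients written", len(records))
    return records, paths


def preprocess_stage(config: RunConfig, series: pd.DataFrame, patients: pd.DataFrame,
                     out_dir: Path):
    catalog = cohort.variable_catalog(config.cohort.n_vars)
    required = catalog["variable"].to_list()
    wide, flagged = preprocess.select_common_features(series, required, patients)
    daily = catalog.loc[catalog["sampling"] == "daily", "variable"].to_list()
    wide = preprocess.resample_daily_to_hourly(wide, daily, limit=config.prep.daily_ffill_limit)
    stats = preprocess.compute_missingness(wide)
    retained = preprocess.filter_patients(stats, config.prep.p_id_max, config.prep.p_ir_max)
    logger.info("[preprocess] retained %d / %d patients", len(retained), len(stats))
    if not retained:
        raise DataError("empty cohort: the missingness filter excluded every patient")
    pts = patients[patients["patient_id"].astype(str).isin([str(r) for r in retained])]
    ws = preprocess.build_windows(
        wide.loc[retained], pts, horizon_steps=config.prep.horizon_steps,
        tau=config.prep.tau, max_windows=config.prep.max_windows,
        window_selection=config.prep.window_selection,
    )
    paths = ws.save(out_dir)
    stats_path = out_dir / "missingness.csv"
    stats.to_csv(stats_path, index=False)
    paths["missingness"] = stats_path
    return ws, pts, paths


def cv_stage(config: RunConfig, ws: preprocess.LabeledWindowSet, patients: pd.DataFrame,
             out_dir: Path):
    models, pooled, folds, scalers = model.run_cv(ws, patients, config.model)
    paths = {}
    for k, est in enumerate(models, start=1):
        hist = est.history_.rename(columns={"train_cost": "train_cost", "val_cost": "val_cost"})
        p = out_dir / f"history_fold{k}.csv"
        hist.to_csv(p, index=False)
        paths[f"history_fold{k}"] = p
        ckpt = model.save_model(est, scalers[k - 1], out_dir / f"model_fold{k}")
        paths[f"model_fold{k}"] = ckpt["weights"]
    p = out_dir / "predictions.csv"
    pooled.to_csv(p, index=False)
    paths["predictions"] = p
    p = out_dir / "folds.csv"
    folds.to_csv(p, index=False)
    paths["folds"] = p
    val_costs = [float(est.history_["val_cost"].min()) if len(est.history_) else float("nan")
                 for est in models]
    logger.info("[cv] best validation costs per fold: %s",
                ", ".join(f"{c:.3f}" for c in val_costs))
    return pooled, paths


def evaluate_stage(config: RunConfig, pooled: pd.DataFrame, out_dir: Path):
    ev = config.eval
    tauc = evaluate.tauc_table(pooled, ev.horizons, ev.control_matching, ev.score)
    traj = evaluate.risk_trajectories(pooled, horizon_for_risk=ev.horizon_for_risk)
    curves = {}
    for u in (1, 0):
        pids = pooled.loc[pooled["u"] == u, "patient_id"].astype(str).unique()
        for pid in pids[: ev.curve_patients]:
            c, summary = evaluate.patient_cdf_curves(pooled, pid)
            curves[pid] = pd.merge(c, summary, on="prediction_hour", how="left")
    paths = evaluate.write_evaluation(out_dir, tauc, traj, curves)
    try:
        paths.update(_plots(out_dir, tauc, traj))
    except Exception as err:  # plotting must never sink the pipeline
        logger.warning("[evaluate] plotting failed: %s", err)
    return tauc, paths


def _plots(out_dir: Path, tauc: pd.DataFrame, traj: pd.DataFrame) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ok = tauc[tauc["computable"]]
    ax.plot(ok["horizon"], ok["auc"], "o-")
    ax.set_xlabel("time to event (h)")
    ax.set_ylabel("AUC")
    ax.set_ylim(0.0, 1.0)
    ax.set_title("Time-dependent AUC")
    fig.tight_layout()
    p = out_dir / "tauc.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["tauc_plot"] = p

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for name, color in (("event", "tab:red"), ("censored", "tab:blue")):
        sub = traj[traj["group"] == name].dropna(subset=["median"])
        ax.plot(sub["remaining"], sub["median"], color=color, label=name)
        ax.fill_between(sub["remaining"], sub["q25"], sub["q75"], color=color, alpha=0.25)
    ax.invert_xaxis()
    ax.set_xlabel("remaining time (h)")
    ax.set_ylabel("risk probability")
    ax.legend()
    fig.tight_layout()
    p = out_dir / "trajectories.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["trajectories_plot"] = p
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest (also written to disk)."""
    config.validate()
    config = config.seeded()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_paths: dict = {}
    counts: dict = {}
    stage = "simulate"
    try:
        records, paths = simulate_stage(config, out_dir)
        all_paths.update(paths)
        counts["patients"] = len(records)
        series, patients = cohort.read_cohort(out_dir)
        counts["series_rows"] = len(series)

        stage = "preprocess"
        ws, pts, paths = preprocess_stage(config, series, patients, out_dir)
        all_paths.update(paths)
        counts["retained_patients"] = len(pts)
        counts["observations"] = ws.n_observations

        stage = "cv"
        pooled, paths = cv_stage(config, ws, pts, out_dir)
        all_paths.update(paths)
        counts["pooled_predictions"] = len(pooled)

        stage = "evaluate"
        tauc, paths = evaluate_stage(config, pooled, out_dir)
        all_paths.update(paths)
        counts["tauc_rows"] = len(tauc)
    except Exception as err:
        logger.error("[%s] stage failed: %s", stage, err)
        raise

    manifest = {
        "config": _config_echo(config),
        "seed": config.seed,
        "stage_seeds": {k: config.seed + v for k, v in SEED_OFFSETS.items()},
        "counts": counts,
        "outputs": {k: {"path": str(p), "sha256": _digest(Path(p))}
                    for k, p in sorted(all_paths.items())},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_echo(config: RunConfig) -> dict:
    def as_dict(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: as_dict(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {
        "cohort": as_dict(config.cohort),
        "prep": as_dict(config.prep),
        "model": as_dict(config.model),
        "eval": as_dict(config.eval),
        "out_dir": config.out_dir,
        "seed": config.seed,
    }
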