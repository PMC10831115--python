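"""File formats and configuration for cohort and results artifacts.

All artifacts are delimited text.  A simulated cohort directory contains:

* ``subjects.csv`` — one row per subject: ``subject_id, age, sex, bmi, ecog,
  ecog_dichot, group, dose_event, hospitalization_4wk, death_6mo``.
* ``activity/<subject_id>.csv`` — one file per subject holding both the
  run-length-encoded posture stream and the step events, with columns
  ``day_index, record, start_s, duration_s, state``.  ``record`` is ``bout``
  (``state`` named, ``duration_s`` integer seconds) or ``step`` (``start_s``
  the fractional second of the step; other fields empty).
* ``config.yaml`` — the configuration that produced the run (provenance).

Biomarker tables are plain CSV with a stable column order
(``subject_id, day_index`` then the nine feature columns).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomarkers import DEFAULT_MAX_GAP_S, FEATURE_NAMES
from .cohort import (
    STATE_CODES,
    STATE_NAMES,
    ActivityDay,
    CohortConfig,
    TrajectoryParams,
)

__all__ = [
    "PipelineConfig",
    "subjects_frame",
    "write_cohort",
    "read_cohort",
    "write_biomarkers",
    "read_biomarkers",
    "load_config",
    "dump_config",
]


def subjects_frame(cohort) -> pd.DataFrame:
    """Subject table (one row per subject) for a generated cohort."""
    rows = []
    for profile, _days in cohort:
        rows.append(
            {
                "subject_id": profile.subject_id,
                "age": round(profile.age, 1),
                "sex": profile.sex,
                "bmi": round(profile.bmi, 1),
                "ecog": profile.ecog,
                "ecog_dichot": profile.ecog_dichot,
                "group": profile.group,
                "dose_event": profile.dose_event,
                "hospitalization_4wk": profile.hospitalization_4wk,
                "death_6mo": profile.death_6mo,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "age",
            "sex",
            "bmi",
            "ecog",
            "ecog_dichot",
            "group",
            "dose_event",
            "hospitalization_4wk",
            "death_6mo",
        ],
    )


def _activity_frame(days: list[ActivityDay]) -> pd.DataFrame:
    frames = []
    for day in days:
        bouts = pd.DataFrame(
            {
                "day_index": day.day_index,
                "record": "bout",
                "start_s": day.bout_starts,
                "duration_s": day.bout_durations,
                "state": [STATE_NAMES[int(s)] for s in day.bout_states],
            }
        )
        steps = pd.DataFrame(
            {
                "day_index": day.day_index,
                "record": "step",
                "start_s": np.round(day.step_times, 3),
                "duration_s": "",
                "state": "",
            }
        )
        frames.append(bouts)
        frames.append(steps)
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort, out_dir, config: CohortConfig | None = None, create: bool = True) -> Path:
    """Write a cohort to ``out_dir`` (subjects table, per-subject activity files,
    and the generating config for provenance).  Returns the directory path."""
    out = Path(out_dir)
    if not out.exists():
        if not create:
            raise FileNotFoundError(f"output directory {out} does not exist")
        out.mkdir(parents=True)
    subjects_frame(cohort).to_csv(out / "subjects.csv", index=False)
    act = out / "activity"
    act.mkdir(exist_ok=True)
    for profile, days in cohort:
        _activity_frame(days).to_csv(act / f"{profile.subject_id}.csv", index=False)
    if config is not None:
        dump_config({"cohort": _cohort_config_dict(config)}, out / "config.yaml")
    return out


def _parse_activity(path: Path, subject_id: str) -> list[ActivityDay]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"malformed activity file {path}: {exc}") from exc
    required = {"day_index", "record", "start_s", "duration_s", "state"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    days = []
    for day_index, grp in df.groupby("day_index"):
        bouts = grp[grp["record"] == "bout"].sort_values("start_s")
        steps = grp[grp["record"] == "step"].sort_values("start_s")
        try:
            states = np.array([STATE_CODES[s] for s in bouts["state"]], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"{path}: unknown posture state {exc} in day {day_index}")
        days.append(
            ActivityDay(
                subject_id=subject_id,
                day_index=int(day_index),
                bout_starts=bouts["start_s"].to_numpy(dtype=np.int64),
                bout_durations=bouts["duration_s"].to_numpy(dtype=np.int64),
                bout_states=states,
                step_times=steps["start_s"].to_numpy(dtype=float),
            )
        )
    return days


def read_cohort(in_dir) -> list[tuple[dict, list[ActivityDay]]]:
    """Read a cohort directory back into (subject-row dict, activity days) pairs."""
    root = Path(in_dir)
    subjects = pd.read_csv(root / "subjects.csv")
    out = []
    for row in subjects.to_dict("records"):
        sid = row["subject_id"]
        days = _parse_activity(root / "activity" / f"{sid}.csv", sid)
        out.append((row, days))
    return out


def write_biomarkers(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = ["subject_id", "day_index", *FEATURE_NAMES]
    table[cols].to_csv(path, index=False)
    return path


def read_biomarkers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "day_index", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"biomarker table {path} missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run configuration (cohort, extraction and analysis knobs)."""

    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    max_gap_s: float = DEFAULT_MAX_GAP_S
    auc_threshold: float = 0.80
    p_max: float = 0.05
    d_min: float = 0.8
    predictor_mode: str = "change"
    model_day: int = 6
    seed: int | None = None
    verbosity: str = "info"

    def resolved_cohort(self) -> CohortConfig:
        cfg = self.cohort
        if self.seed is not None:
            cfg = dataclasses.replace(cfg, seed=self.seed)
        return cfg


def _cohort_config_dict(cfg: CohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["trajectory_params"] = {
        g: dataclasses.asdict(p) for g, p in cfg.trajectory_params.items()
    }
    d["ecog_probs_by_group"] = {g: list(map(float, v)) for g, v in cfg.ecog_probs_by_group.items()}
    return d


def _cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "trajectory_params" in d:
        d["trajectory_params"] = {
            g: TrajectoryParams(**p) for g, p in d["trajectory_params"].items()
        }
    if "ecog_probs_by_group" in d:
        d["ecog_probs_by_group"] = {g: tuple(v) for g, v in d["ecog_probs_by_group"].items()}
    return CohortConfig(**d)


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["cohort"] = _cohort_config_dict(cfg.cohort)
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "cohort" in d and not isinstance(d["cohort"], CohortConfig):
        d["cohort"] = _cohort_config_from_dict(d["cohort"])
    return PipelineConfig(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(cfg, path) -> Path:
    """Serialise a PipelineConfig (or a plain dict) to YAML."""
    data = config_to_dict(cfg) if isinstance(cfg, PipelineConfig) else cfg
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
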