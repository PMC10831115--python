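"""End-to-end orchestration: simulate -> extract -> analyze.

The analysis stage mirrors the study workflow: trajectory-ratio and day-wise
group comparisons, the earliest-day AUC search for the sensor (MBF) model,
the three-model comparison (ECOG, MBF, ECOG+MBF) on the selected day, the
CRI from the combined model's fitted probabilities, and Youden-optimal
cut-point metrics including the prevalence-adjusted PPV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as rm
from .biomarkers import biomarker_table
from .cohort import CohortConfig, generate_cohort
from .io import PipelineConfig, subjects_frame
from .trajectories import daywise_profile, group_compare, trajectory_features

__all__ = ["simulate_tables", "analyze", "write_results", "summarize"]

log = logging.getLogger("chemoresilience")


def simulate_tables(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and return (subjects table, daily biomarker table)."""
    cohort = generate_cohort(config)
    return subjects_frame(cohort), biomarker_table(cohort)


def _trajectory_comparisons(biomarkers: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Group contrasts of the baseline-to-endpoint trajectory ratios."""
    traj = trajectory_features(biomarkers)
    labels = subjects.set_index("subject_id")["group"]
    rows = []
    for feature, grp in traj.groupby("feature_name"):
        grp = grp.set_index("subject_id")
        lab = labels.reindex(grp.index).to_numpy()
        try:
            cmp_ = group_compare(grp["ratio_change"].to_numpy(), lab, feature, "trajectory")
        except ValueError:
            log.warning("trajectory contrast for %s skipped (too few usable subjects)", feature)
            continue
        rows.append(cmp_.as_dict())
    return pd.DataFrame(rows)


def analyze(
    biomarkers: pd.DataFrame,
    subjects: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full statistical analysis on extracted biomarker tables.

    Returns a results bundle (plain dict) with the day-wise profile, the
    trajectory contrasts, the earliest-day search, the three model fits on
    the analysis day, per-subject CRI scores and the cut-point metrics.
    """
    config = config or PipelineConfig()
    required = {"subject_id", "group"}
    missing = required - set(subjects.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")

    daywise = daywise_profile(biomarkers, subjects)
    traj_cmp = _trajectory_comparisons(biomarkers, subjects)

    search = rm.earliest_day_search(
        biomarkers,
        subjects,
        rm.ModelSpec.mbf(mode=config.predictor_mode),
        auc_threshold=config.auc_threshold,
    )
    analysis_day = search.earliest_day if search.earliest_day is not None else config.model_day
    fits = rm.compare_models(biomarkers, subjects, analysis_day, mode=config.predictor_mode)

    combined = fits["ECOG_MBF"]
    labels = (
        subjects.set_index("subject_id").reindex(combined.subject_ids)["group"] == "nonresilient"
    ).to_numpy(dtype=float)
    cri = pd.DataFrame(
        {
            "subject_id": combined.subject_ids,
            "cri": combined.cri_scores,
            "group": np.where(labels == 1, "nonresilient", "resilient"),
        }
    )
    cutpoint = rm.optimal_cutpoint(combined.cri_scores, labels)
    cri_contrast = group_compare(cri["cri"].to_numpy(), cri["group"].to_numpy(), "cri", analysis_day)

    return {
        "daywise": daywise,
        "trajectory_comparisons": traj_cmp,
        "earliest_day": search,
        "analysis_day": analysis_day,
        "fits": fits,
        "cri": cri,
        "cri_contrast": cri_contrast,
        "cutpoint": cutpoint,
    }


def _fit_dict(fit: rm.ModelFit) -> dict:
    return {
        "predictors": fit.predictor_names,
        "coefficients": [float(c) for c in fit.coefficients],
        "converged": fit.converged,
        "separation_flag": fit.separation_flag,
        "auc": float(fit.auc),
    }


def write_results(results: dict, out_dir, create: bool = True) -> Path:
    """Write a results bundle as delimited-text / JSON files under ``out_dir``."""
    out = Path(out_dir)
    if not out.exists():
        if not create:
            raise FileNotFoundError(f"output directory {out} does not exist")
        out.mkdir(parents=True)
    results["daywise"].to_csv(out / "daywise_comparisons.csv", index=False)
    results["trajectory_comparisons"].to_csv(out / "trajectory_comparisons.csv", index=False)
    results["cri"].to_csv(out / "cri.csv", index=False)
    search = results["earliest_day"]
    pd.DataFrame(
        {"day_index": list(search.per_day_auc), "auc": list(search.per_day_auc.values())}
    ).to_csv(out / "per_day_auc.csv", index=False)
    bundle = {
        "earliest_day": search.earliest_day,
        "auc_threshold": search.auc_threshold,
        "analysis_day": results["analysis_day"],
        "models": {name: _fit_dict(fit) for name, fit in results["fits"].items()},
        "cutpoint": dataclasses.asdict(results["cutpoint"]),
        "cri_contrast": results["cri_contrast"].as_dict(),
    }
    with open(out / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2)
    (out / "summary.txt").write_text(summarize(results))
    return out


def summarize(results: dict) -> str:
    """Human-readable run summary in the study's reporting style."""
    search = results["earliest_day"]
    fits = results["fits"]
    cut = results["cutpoint"]
    cc = results["cri_contrast"]
    lines = ["Chemotherapy resilience analysis", "=" * 34]
    aucs = ", ".join(
        f"d{d}={a:.2f}" if np.isfinite(a) else f"d{d}=NA" for d, a in sorted(search.per_day_auc.items())
    )
    lines.append(f"Per-day MBF AUC: {aucs}")
    if search.earliest_day is None:
        lines.append(f"No day reached AUC >= {search.auc_threshold:.2f}")
    else:
        lines.append(
            f"Earliest day with AUC >= {search.auc_threshold:.2f}: day {search.earliest_day}"
        )
    lines.append(f"Analysis day: {results['analysis_day']}")
    lines.append(
        "Model AUCs: "
        + ", ".join(f"{name}={fit.auc:.2f}" for name, fit in fits.items())
    )
    lines.append(
        f"CRI (resilient {cc.mean_resilient:.2f} +/- {cc.sd_resilient:.2f} vs "
        f"non-resilient {cc.mean_nonresilient:.2f} +/- {cc.sd_nonresilient:.2f}, "
        f"p = {cc.p_value:.2g}, d = {abs(cc.cohens_d):.2f})"
    )
    lines.append(
        f"Optimal CRI cut-off {cut.threshold:.2f}: sensitivity {cut.sensitivity:.0%}, "
        f"specificity {cut.specificity:.0%}, PPV {cut.ppv:.0%}, adjusted PPV {cut.adjusted_ppv:.0%} "
        f"(prevalence {cut.prevalence:.0%})"
    )
    return "\n".join(lines) + "\n"
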