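"""Trajectory change statistics and day-wise two-group comparisons.

The trajectory of each daily biomarker over the monitoring window is
summarised by the relative change from baseline (day 1, the first
chemotherapy day) to the endpoint (last monitored day):

    ratio = (endpoint - baseline) / baseline

Group contrasts (resilient vs non-resilient) use a two-sample t-test (Welch
by default) and Cohen's d with pooled, (n-1)-weighted standard deviation.
The sign convention is resilient minus non-resilient: a positive d on a
feature whose decline marks frailty means the non-resilient group fared
worse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import FEATURE_NAMES

__all__ = [
    "TrajectoryFeature",
    "GroupComparison",
    "trajectory_ratio",
    "cohens_d",
    "group_compare",
    "trajectory_features",
    "daywise_profile",
]

RESILIENT, NONRESILIENT = "resilient", "nonresilient"


@dataclass
class TrajectoryFeature:
    """Baseline-to-endpoint relative change of one biomarker for one subject."""

    subject_id: str
    feature_name: str
    baseline_value: float
    endpoint_value: float
    ratio_change: float  # NaN when missing
    missing: bool = False


@dataclass
class GroupComparison:
    """Two-group contrast of one feature (a single day or the trajectory ratio)."""

    feature_name: str
    day_index: object  # int day or "trajectory"
    n_resilient: int
    n_nonresilient: int
    mean_resilient: float
    sd_resilient: float
    mean_nonresilient: float
    sd_nonresilient: float
    t_statistic: float
    p_value: float
    cohens_d: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def trajectory_ratio(baseline: float, endpoint: float) -> float:
    """(endpoint - baseline) / baseline; NaN when the baseline is zero."""
    if baseline == 0 or not np.isfinite(baseline):
        return float("nan")
    return (endpoint - baseline) / baseline


def cohens_d(resilient: np.ndarray, nonresilient: np.ndarray) -> float:
    """Cohen's d with pooled (n-1)-weighted SD; sign = resilient - nonresilient."""
    a = np.asarray(resilient, dtype=float)
    b = np.asarray(nonresilient, dtype=float)
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def group_compare(
    values,
    labels,
    feature_name: str = "",
    day_index="trajectory",
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sample comparison of a per-subject quantity between outcome groups.

    ``labels`` holds group names (``"resilient"`` / ``"nonresilient"``).
    Welch's t-test by default (``equal_var=True`` for the pooled-variance
    variant).  Missing values are dropped per group (available-case analysis);
    each group must retain at least two subjects.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    res = values[labels == RESILIENT]
    non = values[labels == NONRESILIENT]
    res = res[np.isfinite(res)]
    non = non[np.isfinite(non)]
    for name, grp in ((RESILIENT, res), (NONRESILIENT, non)):
        if grp.size < 2:
            raise ValueError(
                f"group {name!r} has {grp.size} usable subject(s); need >= 2 for {feature_name or 'comparison'}"
            )
    t, p = stats.ttest_ind(res, non, equal_var=equal_var)
    return GroupComparison(
        feature_name=feature_name,
        day_index=day_index,
        n_resilient=res.size,
        n_nonresilient=non.size,
        mean_resilient=float(res.mean()),
        sd_resilient=float(res.std(ddof=1)),
        mean_nonresilient=float(non.mean()),
        sd_nonresilient=float(non.std(ddof=1)),
        t_statistic=float(t),
        p_value=float(p),
        cohens_d=cohens_d(res, non),
    )


def _pivot(biomarkers: pd.DataFrame, feature: str) -> pd.DataFrame:
    return biomarkers.pivot(index="subject_id", columns="day_index", values=feature)


def trajectory_features(
    biomarkers: pd.DataFrame,
    endpoint_day: int | None = None,
    features=FEATURE_NAMES,
) -> pd.DataFrame:
    """Per-subject baseline-to-endpoint relative change for each biomarker.

    Baseline is day 1; the endpoint defaults to the last day present.  A zero
    (or missing) baseline yields a missing ratio, flagged rather than dropped.
    """
    out = []
    for feature in features:
        wide = _pivot(biomarkers, feature)
        end = endpoint_day if endpoint_day is not None else int(wide.columns.max())
        for sid in wide.index:
            base = wide.at[sid, 1] if 1 in wide.columns else float("nan")
            endv = wide.at[sid, end] if end in wide.columns else float("nan")
            ratio = trajectory_ratio(base, endv) if np.isfinite(base) and np.isfinite(endv) else float("nan")
            out.append(
                {
                    "subject_id": sid,
                    "feature_name": feature,
                    "baseline_value": base,
                    "endpoint_value": endv,
                    "ratio_change": ratio,
                    "missing": not np.isfinite(ratio),
                }
            )
    return pd.DataFrame(out)


def daywise_profile(
    biomarkers: pd.DataFrame,
    subjects: pd.DataFrame,
    alpha: float = 0.05,
    features=FEATURE_NAMES,
    equal_var: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-(feature, day) group comparisons over the whole monitoring window.

    Returns one row per feature and day with group means, standard errors,
    Welch t statistics, p-values, Cohen's d and a significance flag at
    ``alpha``.  No multiple-testing correction is applied by default (the flag
    marks per-day, per-feature tests); ``bh_correct=True`` switches the flag
    to Benjamini-Hochberg-adjusted discoveries across all cells.  Cells where
    either group has fewer than two usable values are flagged as missing.
    """
    labels = subjects.set_index("subject_id")["group"]
    rows = []
    for feature in features:
        wide = _pivot(biomarkers, feature)
        lab = labels.reindex(wide.index).to_numpy()
        for day in sorted(wide.columns):
            vals = wide[day].to_numpy(dtype=float)
            try:
                cmp_ = group_compare(vals, lab, feature, int(day), equal_var=equal_var)
            except ValueError:
                rows.append(
                    {
                        "feature_name": feature,
                        "day_index": int(day),
                        "missing": True,
                        "p_value": float("nan"),
                        "significant": False,
                    }
                )
                continue
            d = cmp_.as_dict()
            d["se_resilient"] = d["sd_resilient"] / np.sqrt(d["n_resilient"])
            d["se_nonresilient"] = d["sd_nonresilient"] / np.sqrt(d["n_nonresilient"])
            d["missing"] = False
            rows.append(d)
    out = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        ok = out["p_value"].notna()
        flags = np.zeros(len(out), dtype=bool)
        if ok.any():
            flags[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], alpha=alpha, method="fdr_bh")[0]
        out["significant"] = flags
    else:
        out["significant"] = out["p_value"] < alpha
    return out
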