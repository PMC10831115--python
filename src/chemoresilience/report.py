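"""Figure-style reports: day-wise group profiles, ROC curves, CRI separation."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .biomarkers import FEATURE_NAMES

__all__ = ["plot_daywise", "plot_roc", "plot_cri", "write_report"]


def plot_daywise(daywise: pd.DataFrame, path) -> Path:
    """Per-day group means with standard errors for each biomarker; asterisks
    mark days with a significant group difference."""
    features = [f for f in FEATURE_NAMES if f in set(daywise["feature_name"])]
    ncols = 3
    nrows = int(np.ceil(len(features) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 2.6 * nrows), squeeze=False)
    for ax, feature in zip(axes.ravel(), features):
        sub = daywise[(daywise["feature_name"] == feature) & (~daywise.get("missing", False))]
        ax.errorbar(
            sub["day_index"], sub["mean_resilient"], yerr=sub["se_resilient"],
            color="tab:blue", label="resilient", capsize=2,
        )
        ax.errorbar(
            sub["day_index"], sub["mean_nonresilient"], yerr=sub["se_nonresilient"],
            color="tab:red", label="non-resilient", capsize=2,
        )
        sig = sub[sub["significant"]]
        if len(sig):
            ymax = max(sub["mean_resilient"].max(), sub["mean_nonresilient"].max())
            ax.plot(sig["day_index"], [ymax * 1.05] * len(sig), "k*", ms=6)
        ax.set_title(feature, fontsize=9)
        ax.set_xlabel("day")
    for ax in axes.ravel()[len(features):]:
        ax.axis("off")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_roc(fits: dict, labels: np.ndarray, path) -> Path:
    """ROC curves of the ECOG / MBF / combined models on the analysis day."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, fit in fits.items():
        fpr, tpr, _ = roc_curve(labels, fit.cri_scores)
        ax.plot(fpr, tpr, label=f"{name} (AUC {fit.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_cri(cri: pd.DataFrame, threshold: float, path) -> Path:
    """Per-group CRI distributions with the optimal cut-off line."""
    fig, ax = plt.subplots(figsize=(4.0, 4.0))
    groups = ["resilient", "nonresilient"]
    data = [cri.loc[cri["group"] == g, "cri"] for g in groups]
    ax.boxplot(data, tick_labels=groups, widths=0.5)
    for i, vals in enumerate(data, start=1):
        ax.plot(np.full(len(vals), i) + np.random.default_rng(0).uniform(-0.08, 0.08, len(vals)),
                vals, "o", ms=4, alpha=0.6)
    ax.axhline(threshold, color="k", ls="--", lw=0.8, label=f"cut-off {threshold:.2f}")
    ax.set_ylabel("Chemotherapy Resilience Index")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def write_report(results: dict, out_dir) -> list[Path]:
    """Write all three figure files for a results bundle into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cri = results["cri"]
    labels = (cri["group"] == "nonresilient").to_numpy(dtype=float)
    return [
        plot_daywise(results["daywise"], out / "daywise_profile.png"),
        plot_roc(results["fits"], labels, out / "roc_models.png"),
        plot_cri(cri, results["cutpoint"].threshold, out / "cri_groups.png"),
    ]
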