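"""Logistic resilience models, earliest-day AUC search, CRI and cut-point metrics.

Three logistic regressions of non-resilience are compared: baseline ECOG
performance status alone (dichotomised 0 vs 1-2), mobility-derived digital
biomarkers of frailty (MBF) alone, and their combination.  MBF predictors
are, by default, the relative change from baseline (day 1) of walking cadence
(90th percentile) and of total postural transitions, measured on a chosen
monitoring day.  The fitted probability of non-resilience from the combined
model is the Chemotherapy Resilience Index (CRI): a 0-1 score, higher values
meaning poorer expected resilience.

The earliest-day search fits the model for each candidate day and returns the
first day whose in-sample AUC clears a threshold (default 0.80).  Cut-point
metrics at the Youden-optimal CRI threshold include PPV = TP/(TP+FP) and the
prevalence-adjusted PPV

    adjPPV = sens * prev / (sens * prev + (1 - spec) * (1 - prev)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .biomarkers import FEATURE_NAMES
from .trajectories import NONRESILIENT, trajectory_ratio

__all__ = [
    "DEFAULT_MBF_FEATURES",
    "ModelSpec",
    "ModelFit",
    "CutpointMetrics",
    "EarliestDayResult",
    "fit_logistic",
    "auc",
    "select_mbf_features",
    "build_feature_matrix",
    "fit_spec",
    "earliest_day_search",
    "optimal_cutpoint",
    "ppv",
    "adjusted_ppv",
    "compare_models",
]

#: Default sensor feature set: the slowness and weakness markers.
DEFAULT_MBF_FEATURES = ("cadence_p90", "postural_transitions")

#: Combined weakness marker: sit-to-stand plus stand-to-sit counts.
_COMBINED_TRANSITIONS = "postural_transitions"


@dataclass(frozen=True)
class ModelSpec:
    """Predictor set for one logistic model.

    ``name`` is one of ``"ECOG"``, ``"MBF"``, ``"ECOG_MBF"``.  ``mbf_features``
    lists sensor features (daily biomarker names, or ``"postural_transitions"``
    for the summed transition counts) supplying day-``day_index`` predictors;
    ``mode`` selects relative change from baseline (``"change"``, default) or
    raw day-``day_index`` values (``"raw"``).
    """

    name: str
    day_index: int = 6
    mbf_features: tuple[str, ...] = DEFAULT_MBF_FEATURES
    use_ecog: bool = False
    mode: str = "change"

    def __post_init__(self):
        if self.name == "ECOG" and self.mbf_features:
            object.__setattr__(self, "mbf_features", ())
        if self.name in ("MBF", "ECOG_MBF") and not self.mbf_features:
            raise ValueError(f"{self.name} spec needs at least one sensor feature")
        if self.mode not in ("change", "raw"):
            raise ValueError("mode must be 'change' or 'raw'")

    @classmethod
    def ecog(cls) -> "ModelSpec":
        return cls("ECOG", mbf_features=(), use_ecog=True)

    @classmethod
    def mbf(cls, day_index: int = 6, mbf_features=DEFAULT_MBF_FEATURES, mode="change") -> "ModelSpec":
        return cls("MBF", day_index, tuple(mbf_features), use_ecog=False, mode=mode)

    @classmethod
    def ecog_mbf(cls, day_index: int = 6, mbf_features=DEFAULT_MBF_FEATURES, mode="change") -> "ModelSpec":
        return cls("ECOG_MBF", day_index, tuple(mbf_features), use_ecog=True, mode=mode)


@dataclass
class ModelFit:
    """A fitted logistic model with its CRI scores and in-sample AUC."""

    spec: ModelSpec | None
    predictor_names: list[str]
    coefficients: np.ndarray  # intercept first
    converged: bool
    separation_flag: bool
    cri_scores: np.ndarray
    auc: float
    subject_ids: list[str] = field(default_factory=list)


@dataclass
class CutpointMetrics:
    """Confusion matrix and derived metrics at one CRI threshold (score >= threshold -> non-resilient)."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    adjusted_ppv: float
    prevalence: float
    youden_j: float


@dataclass
class EarliestDayResult:
    """Per-day in-sample AUCs and the earliest day clearing the AUC threshold."""

    per_day_auc: dict[int, float]
    earliest_day: int | None
    auc_threshold: float
    fits: dict[int, ModelFit] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# core estimation
# ---------------------------------------------------------------------------


def auc(scores, labels) -> float:
    """Area under the ROC curve: P(random positive outscores a random negative),
    ties counted 1/2 (the Mann-Whitney identity).  Labels are 0/1."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _ridge_logistic(X: np.ndarray, y: np.ndarray, alpha: float, n_iter: int = 200) -> np.ndarray:
    """Newton-iterated ridge-penalised logistic fit (intercept unpenalised)."""
    beta = np.zeros(X.shape[1])
    pen = np.full(X.shape[1], alpha)
    pen[0] = 0.0
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        grad = X.T @ (y - p) - pen * beta
        hess = (X * w[:, None]).T @ X + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def fit_logistic(
    features,
    labels,
    predictor_names: list[str] | None = None,
    subject_ids: list[str] | None = None,
    ridge_alpha: float = 1e-4,
    spec: ModelSpec | None = None,
) -> ModelFit:
    """Maximum-likelihood logistic regression of non-resilience (label 1).

    Complete or quasi-complete separation is detected (non-convergence or a
    diverging linear predictor) and handled with a small ridge penalty
    (``ridge_alpha``); ``separation_flag`` records that the fitted
    probabilities are then saturated and the coefficients regularised rather
    than true MLEs.  Deterministic given inputs.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot fit")
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        ids = subject_ids or [str(i) for i in range(len(y))]
        offenders = [ids[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"non-finite features for subjects: {offenders}")

    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    params = None
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = np.asarray(res.params)
            converged = bool(res.mle_retvals.get("converged", True))
            eta = Xc @ params
            if not converged or np.max(np.abs(eta)) > 30:
                separation = True
        except Exception:
            separation = True
    if separation:
        params = _ridge_logistic(Xc, y, ridge_alpha)
        converged = True
    probs = 1.0 / (1.0 + np.exp(-np.clip(Xc @ params, -500, 500)))
    names = predictor_names or [f"x{i + 1}" for i in range(X.shape[1])]
    return ModelFit(
        spec=spec,
        predictor_names=list(names),
        coefficients=params,
        converged=converged,
        separation_flag=separation,
        cri_scores=probs,
        auc=auc(probs, y),
        subject_ids=list(subject_ids or []),
    )


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


def _feature_values(biomarkers: pd.DataFrame, feature: str) -> pd.DataFrame:
    if feature == _COMBINED_TRANSITIONS:
        df = biomarkers.assign(
            postural_transitions=biomarkers["n_sit_to_stand"] + biomarkers["n_stand_to_sit"]
        )
    else:
        df = biomarkers
    return df.pivot(index="subject_id", columns="day_index", values=feature)


def build_feature_matrix(
    biomarkers: pd.DataFrame,
    subjects: pd.DataFrame,
    spec: ModelSpec,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-subject predictor matrix and 0/1 non-resilience labels for a spec.

    Sensor predictors are the day-``spec.day_index`` values of each feature in
    ``spec.mbf_features`` either as relative change from day 1
    (``mode="change"``) or raw levels; the ECOG predictor is the dichotomised
    performance status (0 vs 1-2).
    """
    subjects = subjects.set_index("subject_id")
    cols = {}
    for feat in spec.mbf_features:
        wide = _feature_values(biomarkers, feat)
        if spec.day_index not in wide.columns:
            raise ValueError(f"day {spec.day_index} absent from biomarker table")
        if spec.mode == "change":
            base = wide[1]
            vals = [
                trajectory_ratio(b, e) for b, e in zip(base.to_numpy(), wide[spec.day_index].to_numpy())
            ]
            cols[f"{feat}_change_d{spec.day_index}"] = pd.Series(vals, index=wide.index)
        else:
            cols[f"{feat}_d{spec.day_index}"] = wide[spec.day_index]
    if spec.use_ecog:
        if "ecog_dichot" in subjects.columns:
            ecog = subjects["ecog_dichot"]
        else:
            ecog = (subjects["ecog"] > 0).astype(float)
        cols["ecog_dichot"] = ecog
    X = pd.DataFrame(cols)
    X = X.loc[sorted(X.index)]
    y = (subjects.reindex(X.index)["group"] == NONRESILIENT).to_numpy(dtype=float)
    return X, y


def fit_spec(biomarkers: pd.DataFrame, subjects: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Assemble predictors for ``spec`` and fit the logistic model."""
    X, y = build_feature_matrix(biomarkers, subjects, spec)
    return fit_logistic(
        X.to_numpy(),
        y,
        predictor_names=list(X.columns),
        subject_ids=list(X.index),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# feature selection and earliest-day search
# ---------------------------------------------------------------------------


def select_mbf_features(
    comparisons: pd.DataFrame,
    p_max: float = 0.05,
    d_min: float = 0.8,
    candidates=FEATURE_NAMES,
) -> list[str]:
    """Sensor features whose group contrast is significant with a large effect.

    ``comparisons`` is a table with ``feature_name``, ``p_value`` and
    ``cohens_d`` columns (e.g. trajectory-ratio contrasts).  Features with
    p < ``p_max`` and \\|d\\| >= ``d_min`` are returned ranked by descending
    \\|d\\|; an empty selection is returned (with a warning) rather than
    raised, the caller decides how to proceed.
    """
    df = comparisons[comparisons["feature_name"].isin(candidates)].copy()
    df = df[(df["p_value"] < p_max) & (df["cohens_d"].abs() >= d_min)]
    if df.empty:
        warnings.warn("no feature passed the significance/effect-size filter", stacklevel=2)
        return []
    df = df.reindex(df["cohens_d"].abs().sort_values(ascending=False).index)
    return list(dict.fromkeys(df["feature_name"]))


def earliest_day_search(
    biomarkers: pd.DataFrame,
    subjects: pd.DataFrame,
    spec_template: ModelSpec | None = None,
    auc_threshold: float = 0.80,
    days=None,
) -> EarliestDayResult:
    """Scan candidate days for the first one whose model clears the AUC bound.

    For each day d (default 2..max monitored day; day 1 is the baseline), the
    template spec is re-pointed at day d, fitted, and its in-sample AUC
    recorded.  Days whose fit fails (e.g. missing features) contribute a
    missing AUC.  ``earliest_day`` is the minimum qualifying day, or None.
    """
    spec_template = spec_template or ModelSpec.mbf()
    if days is None:
        days = range(2, int(biomarkers["day_index"].max()) + 1)
    per_day: dict[int, float] = {}
    fits: dict[int, ModelFit] = {}
    for d in days:
        spec_d = ModelSpec(
            spec_template.name,
            int(d),
            spec_template.mbf_features,
            spec_template.use_ecog,
            spec_template.mode,
        )
        try:
            fit = fit_spec(biomarkers, subjects, spec_d)
        except ValueError:
            per_day[int(d)] = float("nan")
            continue
        per_day[int(d)] = fit.auc
        fits[int(d)] = fit
    qualifying = [d for d, a in per_day.items() if np.isfinite(a) and a >= auc_threshold]
    return EarliestDayResult(
        per_day_auc=per_day,
        earliest_day=min(qualifying) if qualifying else None,
        auc_threshold=auc_threshold,
        fits=fits,
    )


# ---------------------------------------------------------------------------
# cut-point performance
# ---------------------------------------------------------------------------


def ppv(tp: int, fp: int) -> float:
    """Positive predictive value TP / (TP + FP)."""
    if tp + fp == 0:
        return float("nan")
    return tp / (tp + fp)


def adjusted_ppv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Prevalence-adjusted PPV (Bayes form).

    adjPPV = sens*prev / (sens*prev + (1-spec)*(1-prev)).  At a prevalence of
    one half this reduces to sens / (sens + 1 - spec).
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    if den == 0:
        raise ZeroDivisionError("adjusted PPV undefined: denominator is zero")
    return num / den


def optimal_cutpoint(cri_scores, labels, prevalence: float | None = None) -> CutpointMetrics:
    """Youden-optimal CRI threshold with its confusion matrix and metrics.

    The classification rule is score >= threshold -> non-resilient.  The
    threshold maximising Youden's J (sensitivity + specificity - 1) over the
    observed scores is chosen; ties are broken toward the higher threshold,
    i.e. toward higher specificity.  ``prevalence`` defaults to the sample
    positive fraction and feeds the adjusted PPV.
    """
    scores = np.asarray(cri_scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("cut-point needs both classes present")
    pos = int(y.sum())
    neg = int(y.size - pos)
    prev = pos / y.size if prevalence is None else prevalence

    best = None
    for thr in np.unique(scores):
        pred = scores >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        sens = tp / pos
        spec = (neg - fp) / neg
        j = sens + spec - 1.0
        # strict improvement, or same J at a higher threshold (higher specificity)
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and thr > best[1]):
            best = (j, float(thr), tp, fp)
    j, thr, tp, fp = best
    fn = pos - tp
    tn = neg - fp
    sens = tp / pos
    spec = tn / neg
    return CutpointMetrics(
        threshold=thr,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv(tp, fp),
        adjusted_ppv=adjusted_ppv(sens, spec, prev),
        prevalence=prev,
        youden_j=j,
    )


# ---------------------------------------------------------------------------
# headline three-model comparison
# ---------------------------------------------------------------------------


def compare_models(
    biomarkers: pd.DataFrame,
    subjects: pd.DataFrame,
    day_index: int = 6,
    mbf_features=DEFAULT_MBF_FEATURES,
    mode: str = "change",
) -> dict[str, ModelFit]:
    """Fit the ECOG-only, MBF-only and combined models on one monitoring day.

    Returns ``{"ECOG": fit, "MBF": fit, "ECOG_MBF": fit}``; the combined
    model's fitted probabilities are the CRI.
    """
    specs = {
        "ECOG": ModelSpec.ecog(),
        "MBF": ModelSpec.mbf(day_index, mbf_features, mode),
        "ECOG_MBF": ModelSpec.ecog_mbf(day_index, mbf_features, mode),
    }
    return {name: fit_spec(biomarkers, subjects, spec) for name, spec in specs.items()}
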