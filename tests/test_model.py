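"""Logistic models, AUC, cut-points and adjusted PPV against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import chemoresilience as cr
from chemoresilience.model import (
    ModelSpec,
    adjusted_ppv,
    auc,
    build_feature_matrix,
    compare_models,
    earliest_day_search,
    fit_logistic,
    optimal_cutpoint,
    ppv,
    select_mbf_features,
)

# ---------------------------------------------------------------------------
# AUC: Mann-Whitney pair-counting oracle
# ---------------------------------------------------------------------------


def oracle_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_all_ties_is_half(self):
        assert auc([0.3] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_perfect_ranking(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_toy_pair_count(self):
        scores, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        assert auc(scores, labels) == pytest.approx(0.75)
        assert oracle_auc(scores, labels) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        n=st.integers(4, 200),
        seed=st.integers(0, 2**20),
        ties=st.booleans(),
    )
    def test_matches_pair_counting_oracle(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, n) / 4 if ties else rng.random(n)
        labels = np.zeros(n, dtype=int)
        labels[: n // 2] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(oracle_auc(scores, labels))


# ---------------------------------------------------------------------------
# logistic fit: IRLS oracle, separation, invariances
# ---------------------------------------------------------------------------


def irls_logistic(X, y, n_iter=100):
    """Independent unpenalised IRLS (Fisher scoring) oracle."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xc.shape[1])
    for _ in range(n_iter):
        eta = Xc @ beta
        p = 1 / (1 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        wx = Xc * w[:, None]
        beta_new = np.linalg.solve(Xc.T @ wx, wx.T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


TOY_X = np.array(
    [[0.2, 1.0], [0.5, 0.2], [0.9, 0.4], [1.3, 1.1], [0.4, 0.9], [1.1, 0.3], [1.6, 0.8], [0.7, 1.4]]
)
TOY_Y = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)  # overlapping classes, finite MLE


class TestFitLogistic:
    def test_matches_irls_oracle_on_toy(self):
        fit = fit_logistic(TOY_X, TOY_Y)
        expected = irls_logistic(TOY_X, TOY_Y)
        assert not fit.separation_flag
        np.testing.assert_allclose(fit.coefficients, expected, atol=1e-6)

    def test_no_information_limit_scores_prevalence(self):
        X = np.ones((10, 1))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        fit = fit_logistic(X, y)
        np.testing.assert_allclose(fit.cri_scores, 0.3, atol=1e-6)

    def test_perfect_separation_flagged(self):
        X = np.array([[0.0], [0.1], [0.2], [0.8], [0.9], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        fit = fit_logistic(X, y)
        assert fit.separation_flag
        assert fit.auc == 1.0
        assert np.all((fit.cri_scores >= 0) & (fit.cri_scores <= 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(TOY_X, np.ones(8))

    def test_non_finite_features_name_subjects(self):
        X = TOY_X.copy()
        X[3, 0] = np.nan
        with pytest.raises(ValueError, match="S4"):
            fit_logistic(X, TOY_Y, subject_ids=[f"S{i + 1}" for i in range(8)])

    def test_cri_invariant_to_predictor_shift(self):
        fit1 = fit_logistic(TOY_X, TOY_Y)
        fit2 = fit_logistic(TOY_X + np.array([5.0, -3.0]), TOY_Y)
        np.testing.assert_allclose(fit1.cri_scores, fit2.cri_scores, atol=1e-8)
        assert fit1.coefficients[0] != pytest.approx(fit2.coefficients[0])


# ---------------------------------------------------------------------------
# cut-point metrics and adjusted PPV
# ---------------------------------------------------------------------------


class TestCutpoint:
    def test_separated_scores_reach_perfect_j(self):
        m = optimal_cutpoint([0.2, 0.3, 0.6, 0.9], [0, 0, 1, 1])
        assert m.youden_j == pytest.approx(1.0)
        assert 0.3 < m.threshold <= 0.6
        assert m.sensitivity == m.specificity == 1.0
        assert (m.tp, m.fp, m.tn, m.fn) == (2, 0, 2, 0)

    def test_tie_break_prefers_specificity(self):
        # J = 0.5 at both thresholds 0.4 and 0.9; the higher threshold must win
        m = optimal_cutpoint([0.1, 0.4, 0.6, 0.9], [0, 1, 0, 1])
        assert m.threshold == pytest.approx(0.9)

    def test_ppv_from_confusion_counts(self):
        assert ppv(tp=10, fp=2) == pytest.approx(10 / 12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutpoint([0.1, 0.9], [1, 1])

    def test_adjusted_ppv_equals_sample_ppv_at_sample_prevalence(self):
        rng = np.random.default_rng(5)
        labels = (rng.random(60) < 0.45).astype(float)
        labels[:2] = [0, 1]
        scores = np.clip(0.4 * labels + rng.normal(0.3, 0.2, 60), 0, 1)
        m = optimal_cutpoint(scores, labels)
        assert m.adjusted_ppv == pytest.approx(m.ppv, abs=1e-12)


class TestAdjustedPpv:
    def test_printed_worked_example(self):
        # sensitivity 10/13, specificity 12/14, prevalence 13/27 -> 10/12 = 83%
        assert adjusted_ppv(10 / 13, 12 / 14, 13 / 27) == pytest.approx(10 / 12)

    def test_half_prevalence_reduces_to_bayes_form(self):
        s, sp = 0.7, 0.85
        assert adjusted_ppv(s, sp, 0.5) == pytest.approx(s / (s + 1 - sp))

    def test_perfect_test_gives_one(self):
        for prev in (0.01, 0.5, 0.99):
            assert adjusted_ppv(1.0, 1.0, prev) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            adjusted_ppv(1.2, 0.5, 0.5)
        with pytest.raises(ZeroDivisionError):
            adjusted_ppv(0.0, 1.0, 0.5)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        s=st.floats(0.05, 1.0),
        sp=st.floats(0.05, 1.0),
        prev=st.floats(0.05, 0.95),
        ds=st.floats(0.0, 0.05),
    )
    def test_monotone_in_all_arguments(self, s, sp, prev, ds):
        base = adjusted_ppv(s, sp, prev)
        assert adjusted_ppv(min(s + ds, 1.0), sp, prev) >= base - 1e-12
        assert adjusted_ppv(s, min(sp + ds, 1.0), prev) >= base - 1e-12
        assert adjusted_ppv(s, sp, min(prev + ds, 0.999)) >= base - 1e-12


# ---------------------------------------------------------------------------
# feature selection and day search
# ---------------------------------------------------------------------------


def _comparisons(rows):
    return pd.DataFrame(rows, columns=["feature_name", "p_value", "cohens_d"])


class TestSelectMbfFeatures:
    def test_all_null_yields_empty_with_warning(self):
        df = _comparisons([(f, 1.0, 0.0) for f in cr.FEATURE_NAMES])
        with pytest.warns(UserWarning):
            assert select_mbf_features(df) == []

    def test_vacuous_thresholds_return_all_ranked(self):
        df = _comparisons(
            [("total_steps", 0.5, 0.3), ("cadence_p90", 0.5, -0.9), ("pct_lying", 0.5, 0.5)]
        )
        out = select_mbf_features(df, p_max=1.1, d_min=0.0)
        assert out == ["cadence_p90", "pct_lying", "total_steps"]  # ranked by |d|

    def test_filters_on_significance_and_effect(self):
        df = _comparisons(
            [("total_steps", 0.001, 0.5), ("cadence_p90", 0.01, 0.9), ("pct_lying", 0.2, 1.5)]
        )
        assert select_mbf_features(df, p_max=0.05, d_min=0.8) == ["cadence_p90"]

    def test_default_cohort_selects_slowness_and_weakness(self, study_tables):
        subjects, bio = study_tables
        prof = cr.daywise_profile(bio, subjects)
        day6 = prof[prof["day_index"] == 6]
        selected = select_mbf_features(day6, p_max=0.05, d_min=0.8)
        assert set(selected) & {"cadence_p90", "n_sit_to_stand", "n_stand_to_sit"}


class TestEarliestDaySearch:
    def test_null_cohort_finds_no_day(self):
        params = {
            "resilient": cr.TrajectoryParams(3, 0.3, 6, 1.0, 0.0),
            "nonresilient": cr.TrajectoryParams(3, 0.3, 6, 1.0, 0.0),
        }
        subjects, bio = cr.simulate_tables(
            cr.CohortConfig(n_subjects=40, prop_nonresilient=0.5, seed=9, trajectory_params=params)
        )
        res = earliest_day_search(bio, subjects)
        assert res.earliest_day is None

    def test_vacuous_threshold_returns_first_candidate(self, study_tables):
        subjects, bio = study_tables
        res = earliest_day_search(bio, subjects, auc_threshold=0.0)
        assert res.earliest_day == 2

    def test_contrast_cohort_separates_mid_cycle(self):
        subjects, bio = cr.simulate_tables(cr.CohortConfig(n_subjects=200, seed=4))
        res = earliest_day_search(bio, subjects)
        assert res.earliest_day in (5, 6, 7)
        assert res.per_day_auc[6] >= 0.80


class TestCompareModels:
    def _toy_tables(self, oracle_ecog: bool):
        rng = np.random.default_rng(17)
        n = 30
        sids = [f"S{i:03d}" for i in range(n)]
        groups = np.array(["nonresilient" if i < n // 2 else "resilient" for i in range(n)])
        y = (groups == "nonresilient").astype(int)
        rows = []
        for sid, yy in zip(sids, y):
            for day in (1, 6):
                effect = 1.0 if day == 1 else (0.7 if yy else 1.0)
                rows.append(
                    {
                        "subject_id": sid,
                        "day_index": day,
                        "cadence_p90": 90 * effect * rng.lognormal(0, 0.1),
                        "n_sit_to_stand": rng.poisson(20 * effect),
                        "n_stand_to_sit": rng.poisson(20 * effect),
                        "longest_bout_steps": 100,
                        "total_steps": 4000,
                        "pct_sitting": 50.0,
                        "pct_standing": 10.0,
                        "pct_walking": 5.0,
                        "pct_lying": 35.0,
                    }
                )
        bio = pd.DataFrame(rows)
        ecog = y if oracle_ecog else rng.integers(0, 2, n)
        subjects = pd.DataFrame({"subject_id": sids, "group": groups, "ecog_dichot": ecog})
        return bio, subjects

    def test_ecog_as_label_is_a_perfect_predictor(self):
        bio, subjects = self._toy_tables(oracle_ecog=True)
        fits = compare_models(bio, subjects, day_index=6)
        assert fits["ECOG"].auc == 1.0
        assert fits["ECOG"].separation_flag
        assert fits["ECOG_MBF"].auc == 1.0

    def test_combined_model_not_worse_than_ecog_alone(self):
        bio, subjects = self._toy_tables(oracle_ecog=False)
        fits = compare_models(bio, subjects, day_index=6)
        assert fits["ECOG_MBF"].auc >= fits["ECOG"].auc

    def test_null_cohort_aucs_near_chance(self):
        params = {
            "resilient": cr.TrajectoryParams(3, 0.3, 6, 1.0, 0.0),
            "nonresilient": cr.TrajectoryParams(3, 0.3, 6, 1.0, 0.0),
        }
        cfg = cr.CohortConfig(
            n_subjects=200,
            prop_nonresilient=0.5,
            seed=31,
            trajectory_params=params,
            ecog_probs_by_group={
                "resilient": (0.4, 0.4, 0.2),
                "nonresilient": (0.4, 0.4, 0.2),
            },
        )
        subjects, bio = cr.simulate_tables(cfg)
        fits = compare_models(bio, subjects)
        for fit in fits.values():
            assert abs(fit.auc - 0.5) <= 0.1

    def test_feature_matrix_uses_relative_change(self, study_tables):
        subjects, bio = study_tables
        X, y = build_feature_matrix(bio, subjects, ModelSpec.mbf(day_index=6))
        assert list(X.columns) == [
            "cadence_p90_change_d6",
            "postural_transitions_change_d6",
        ]
        wide = bio.pivot(index="subject_id", columns="day_index", values="cadence_p90")
        sid = X.index[0]
        expected = (wide.at[sid, 6] - wide.at[sid, 1]) / wide.at[sid, 1]
        assert X.at[sid, "cadence_p90_change_d6"] == pytest.approx(expected)
        assert y.sum() == 13
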