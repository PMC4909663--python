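"""Statistical pipeline: screen, VIF pruning, RR threshold, bedside score,
diagnostic metrics, cross-validation, multinomial and group comparisons."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from peepabsorb.errors import DegenerateModelError
from peepabsorb.predict import (
    BedsideModelSpec,
    ColumnsModelSpec,
    bedside_score,
    choose_rr_threshold,
    cross_validate,
    diagnostic_metrics,
    fit_multinomial,
    fit_multivariable,
    group_comparisons,
    univariate_screen,
)


def _toy_cohort(n=400, seed=0, rr_effect=True, fl_effect=True):
    """Synthetic analysis table with a complete-vs-other structure driven by
    flow limitation and respiratory rate."""
    rng = np.random.default_rng(seed)
    complete = rng.random(n) < 0.33
    rr = np.where(complete, rng.normal(16, 3, n), rng.normal(22, 4, n))
    if not rr_effect:
        rr = rng.normal(20, 4, n)
    rr = np.clip(np.round(rr), 8, 32)
    ti = rng.normal(1.0, 0.1, n)
    label = np.where(complete, "complete",
                     np.where(rng.random(n) < 0.3, "high", "low"))
    # flow-limitation prevalence gradient across classes (0.97/0.9/0.22)
    fl_prev = np.select([label == "complete", label == "high"], [1.0, 0.9],
                        default=0.22)
    fl = rng.random(n) < (fl_prev if fl_effect else 0.6)
    return pd.DataFrame({
        "label": label,
        "respiratory_rate": rr,
        "expiratory_time": 60.0 / rr - ti,
        "minute_ventilation": 0.5 * rr,
        "flow_limited": fl,
        "age": rng.normal(70, 10, n),
        "female": rng.random(n) < 0.4,
        "bmi": rng.normal(28, 6, n),
        "tidal_volume_per_ibw": rng.normal(8, 1, n),
        "resistance": rng.normal(19, 5, n),
        "elastance": rng.normal(19, 5, n),
        "chronic_pulmonary_disease": rng.random(n) < 0.47,
        "acute_pulmonary_disease": rng.random(n) < 0.52,
        "smoking_history": rng.random(n) < 0.5,
        "pao2_fio2": rng.normal(250, 100, n),
        "supine": rng.random(n) < 0.5,
    })


class TestBedsideScore:
    def test_closed_form_values(self):
        assert bedside_score(False, False) == pytest.approx(
            1.0 / (1.0 + math.exp(5.0)), rel=1e-9)
        assert bedside_score(True, True) == pytest.approx(
            1.0 / (1.0 + math.exp(-1.4)), rel=1e-9)
        assert bedside_score(True, False) == pytest.approx(
            1.0 / (1.0 + math.exp(1.5)), rel=1e-9)
        assert bedside_score(False, False) == pytest.approx(0.0067, abs=5e-4)
        assert bedside_score(True, True) == pytest.approx(0.802, abs=5e-4)

    def test_monotone_in_both_predictors(self):
        for fl in (False, True):
            assert bedside_score(True, fl) > bedside_score(False, fl)
        for rr in (False, True):
            assert bedside_score(rr, True) > bedside_score(rr, False)


class TestDiagnosticMetrics:
    def test_published_fl_row(self):
        """2x2 from the per-class counts: complete 32 FL / 33, others
        29 FL / 67."""
        m = diagnostic_metrics(tp=32, fn=1, fp=29, tn=38)
        assert round(m.sensitivity, 2) == 0.97
        assert round(m.specificity, 2) == 0.57
        assert round(m.ppv, 2) == 0.52
        assert round(m.npv, 2) == 0.97

    def test_perfect_classifier(self):
        m = diagnostic_metrics(tp=30, fn=0, fp=0, tn=70)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1, 1, 1, 1)

    def test_reconstructed_counts(self):
        m = diagnostic_metrics(tp=30, fn=3, fp=10, tn=57)
        assert m.sensitivity == pytest.approx(30 / 33)
        assert m.specificity == pytest.approx(57 / 67)
        assert m.ppv == pytest.approx(0.75)
        assert m.npv == pytest.approx(0.95)

    def test_zero_margin_is_nan_not_error(self):
        m = diagnostic_metrics(tp=0, fn=0, fp=5, tn=5)
        assert math.isnan(m.sensitivity)

    @given(st.integers(0, 80), st.integers(0, 80), st.integers(0, 80),
           st.integers(0, 80))
    @hyp_settings(max_examples=300, deadline=None)
    def test_agrees_with_brute_force_counting(self, tp, fn, fp, tn):
        """Rebuild the patient-level vectors and count every cell by brute
        force; metrics and CI bounds must be consistent."""
        y = np.array([1] * (tp + fn) + [0] * (fp + tn))
        pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
        m = diagnostic_metrics(tp, fn, fp, tn)
        if tp + fn > 0:
            assert m.sensitivity == pytest.approx(
                np.mean(pred[y == 1]))
            assert m.sensitivity_ci[0] <= m.sensitivity <= m.sensitivity_ci[1]
        if fp + tn > 0:
            assert m.specificity == pytest.approx(
                np.mean(1 - pred[y == 0]))


class TestScreenAndFit:
    def test_fl_and_rr_selected_under_generative_model(self):
        screen = univariate_screen(_toy_cohort(n=1000, seed=1))
        assert screen.loc["flow_limited", "selected"]
        assert screen.loc["respiratory_rate", "selected"]
        # flow limitation perfectly predicts the outcome when absent:
        # the screen must survive quasi-separation via the LR fallback
        assert screen.loc["flow_limited", "separation"]

    def test_constant_covariate_not_selected(self):
        df = _toy_cohort(n=200, seed=2)
        df["supine"] = True
        screen = univariate_screen(df)
        assert not screen.loc["supine", "selected"]
        assert screen.loc["supine", "p"] == pytest.approx(1.0)

    def test_null_covariates_rarely_selected(self):
        df = _toy_cohort(n=500, seed=3)
        screen = univariate_screen(df)
        null_covs = ["age", "female", "bmi", "tidal_volume_per_ibw",
                     "resistance", "elastance", "pao2_fio2", "supine"]
        assert screen.loc[null_covs, "selected"].sum() <= 2

    def test_exact_collinearity_pruned_keeping_rr(self):
        """Expiratory time and minute ventilation as exact functions of RR:
        both must be removed, respiratory rate retained."""
        df = _toy_cohort(n=300, seed=4)
        df["expiratory_time"] = 60.0 / df["respiratory_rate"] - 1.0
        df["minute_ventilation"] = 0.5 * df["respiratory_rate"]
        fit = fit_multivariable(
            df, ["respiratory_rate", "expiratory_time", "minute_ventilation",
                 "flow_limited"])
        assert set(fit.dropped_for_vif) == {"expiratory_time",
                                            "minute_ventilation"}
        assert "respiratory_rate" in fit.table.index

    def test_single_covariate_no_pruning(self):
        df = _toy_cohort(n=300, seed=5)
        fit = fit_multivariable(df, ["respiratory_rate"])
        assert fit.dropped_for_vif == []
        assert len(fit.table) == 2           # const + RR

    def test_coefficient_recovery(self):
        """Logistic model generated with known log-odds is recovered."""
        rng = np.random.default_rng(6)
        n = 5000
        rr_low = rng.random(n) < 0.5
        fl = rng.random(n) < 0.6
        eta = -5.0 + 3.5 * rr_low + 2.9 * fl
        y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        df = pd.DataFrame({"rr_low": rr_low.astype(float),
                           "fl": fl.astype(float),
                           "label": np.where(y, "complete", "low")})
        fit = fit_multivariable(df, ["rr_low", "fl"])
        assert fit.table.loc["rr_low", "coef"] == pytest.approx(3.5, abs=0.35)
        assert fit.table.loc["fl", "coef"] == pytest.approx(2.9, abs=0.35)


class TestRRThreshold:
    def test_separated_classes_give_midpoint(self):
        df = pd.DataFrame({
            "label": ["complete"] * 20 + ["low"] * 20,
            "respiratory_rate": [18.0] * 20 + [22.0] * 20,
        })
        res = choose_rr_threshold(df)
        assert res.threshold == pytest.approx(20.0)
        assert res.youden_j == pytest.approx(1.0)

    def test_uninformative_rr_flagged(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "label": np.where(rng.random(400) < 0.4, "complete", "low"),
            "respiratory_rate": np.round(rng.normal(20, 4, 400)),
        })
        res = choose_rr_threshold(df)
        assert res.youden_j < 0.2
        assert res.informative in (True, False)

    def test_degenerate_rr_errors(self):
        df = pd.DataFrame({"label": ["complete", "low"],
                           "respiratory_rate": [20.0, 20.0]})
        with pytest.raises(DegenerateModelError):
            choose_rr_threshold(df)

    def test_generative_threshold_lands_near_20(self):
        hits = 0
        for seed in range(10):
            res = choose_rr_threshold(_toy_cohort(n=300, seed=100 + seed))
            hits += 18.0 <= res.threshold <= 21.0
        assert hits >= 9


class TestCrossValidation:
    def test_constant_model_has_no_discrimination(self):
        df = _toy_cohort(n=300, seed=8)
        df["const_feature"] = 1.0
        cv = cross_validate(df, ColumnsModelSpec(["const_feature"]), k=5,
                            seed=8, bootstrap_reps=50)
        assert cv.auc_corrected == pytest.approx(0.5, abs=0.02)

    def test_self_consistent_generative_auroc(self):
        """Labels drawn from the bedside model's own probabilities: the
        cross-validated AUROC matches the brute-force pairwise AUROC of the
        generating scores."""
        rng = np.random.default_rng(9)
        n = 2000
        rr_low = rng.random(n) < 0.5
        fl = rng.random(n) < 0.6
        p = 1.0 / (1.0 + np.exp(-(-1.5 + 2.2 * rr_low + 1.8 * fl)))
        y = rng.random(n) < p
        df = pd.DataFrame({
            "respiratory_rate": np.where(rr_low, 16.0, 24.0),
            "flow_limited": fl, "label": np.where(y, "complete", "low")})
        # brute-force pairwise comparison oracle on the generating scores
        pos, neg = p[y], p[~y]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
        cv = cross_validate(df, BedsideModelSpec(), k=10, seed=9,
                            bootstrap_reps=50)
        assert cv.auc_corrected == pytest.approx(oracle, abs=0.03)

    def test_corrected_not_above_apparent_beyond_noise(self):
        wins = 0
        for seed in range(10):
            df = _toy_cohort(n=80, seed=200 + seed)
            cv = cross_validate(df, k=5, seed=seed, bootstrap_reps=20)
            wins += cv.auc_corrected <= cv.apparent_auc + 0.02
        assert wins >= 8

    def test_stratification_error(self):
        df = _toy_cohort(n=40, seed=10)
        df.loc[df.index[:39], "label"] = "low"
        df.loc[df.index[39], "label"] = "complete"
        with pytest.raises(DegenerateModelError):
            cross_validate(df, k=10, seed=0)


class TestSecondaryAnalyses:
    def test_multinomial_fl_ordering(self):
        """Flow limitation separates complete from low more strongly than
        high from low; both odds ratios exceed 1."""
        df = _toy_cohort(n=600, seed=11)
        res = fit_multinomial(df, ["respiratory_rate", "flow_limited"])
        or_complete = res[res["class"] == "complete"].loc["flow_limited", "or"]
        or_high = res[res["class"] == "high"].loc["flow_limited", "or"]
        assert or_complete > or_high > 1.0

    def test_multinomial_needs_three_classes(self):
        df = _toy_cohort(n=100, seed=12)
        df["label"] = "low"
        with pytest.raises(DegenerateModelError):
            fit_multinomial(df, ["respiratory_rate"])

    def test_independent_covariate_ci_spans_one(self):
        df = _toy_cohort(n=600, seed=13)
        res = fit_multinomial(df, ["age", "respiratory_rate"])
        row = res[res["class"] == "complete"].loc["age"]
        assert row["or_lo"] < 1.0 < row["or_hi"]

    def test_group_comparisons_identical_vs_separated(self):
        rng = np.random.default_rng(14)
        n = 90
        df = pd.DataFrame({
            "label": ["complete", "high", "low"] * (n // 3),
            "age": rng.normal(70, 10, n),
            "elastance": rng.normal(19, 2, n),
        })
        # separate elastance means by 3 sd across classes
        df.loc[df["label"] == "complete", "elastance"] += 6.0
        df.loc[df["label"] == "high", "elastance"] += 3.0
        res = group_comparisons(df, ["age", "elastance"])
        assert res.loc["age", "p"] > 0.05
        assert res.loc["elastance", "p"] < 0.001

    def test_binary_prevalence_gradient(self):
        rng = np.random.default_rng(15)
        rows = []
        for lab, prev in (("complete", 0.9), ("high", 0.5), ("low", 0.2)):
            for _ in range(30):
                rows.append({"label": lab,
                             "smoking_history": rng.random() < prev})
        res = group_comparisons(pd.DataFrame(rows), ["smoking_history"])
        assert res.loc["smoking_history", "p"] < 0.001
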