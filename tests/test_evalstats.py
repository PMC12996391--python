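"""Metric formulas against oracles: confusion metrics, AUROC, bootstrap,
calibration scores, decision curves, prevalence adjustment, robustness."""

import numpy as np
import pandas as pd
import pytest

from spinesrh import CLASSES
from spinesrh.evalstats import (ConfusionSummary, PrevalenceScenario,
                                ablation_compare, auroc_ovr, brier_scores,
                                cluster_bootstrap_ci, confusion_counts,
                                decision_curve, expected_calibration_error,
                                macro_average, macro_balanced_accuracy,
                                one_random_slide_eval, patch_count_analysis,
                                per_class_metrics,
                                prevalence_adjusted_predictive_values,
                                stratified_reports, compute_metrics_report)
from spinesrh.synth import ReliabilityProfile, make_probability_fixture


class TestPerClassMetrics:
    def test_balanced_accuracy_identity_random_counts(self, rng):
        for _ in range(200):
            cs = ConfusionSummary("meningioma", *rng.integers(1, 50, 4))
            m = per_class_metrics(cs)
            assert m["balanced_accuracy"] == pytest.approx(
                (m["sensitivity"] + m["specificity"]) / 2, abs=1e-10)

    def test_degenerate_counts_give_undefined_markers(self):
        cs = ConfusionSummary("meningioma", tp=0, fp=3, tn=5, fn=0)
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            m = per_class_metrics(cs)
        assert np.isnan(m["sensitivity"])
        assert np.isnan(m["balanced_accuracy"])

    def test_macro_average_identities(self, rng):
        """Mean of per-class BAs equals (macro sens + macro spec)/2 to 1e-10."""
        summaries = [ConfusionSummary(c, *rng.integers(1, 40, 4)) for c in CLASSES]
        metrics = [per_class_metrics(cs) for cs in summaries]
        ba = macro_average([m["balanced_accuracy"] for m in metrics])
        sens = macro_average([m["sensitivity"] for m in metrics])
        spec = macro_average([m["specificity"] for m in metrics])
        assert ba == pytest.approx((sens + spec) / 2, abs=1e-10)

    def test_macro_average_rejects_all_undefined(self):
        with pytest.raises(ValueError):
            macro_average([np.nan] * 4)

    def test_confusion_counts_partition(self, rng):
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        for cs in confusion_counts(y_true, y_pred):
            assert cs.tp + cs.fp + cs.tn + cs.fn == 100
            assert cs.prevalence_count == np.sum(
                y_true == CLASSES.index(cs.class_label))


class TestAUROC:
    def test_perfect_separation_is_one(self):
        scores = np.zeros((20, 4))
        labels = np.repeat(np.arange(4), 5)
        scores[np.arange(20), labels] = 1.0
        out = auroc_ovr(scores, labels)
        assert all(out[c] == pytest.approx(100.0) for c in CLASSES)

    def test_random_scores_near_half(self, rng):
        n = 10_000
        scores = rng.dirichlet(np.ones(4), size=n)
        labels = rng.integers(0, 4, n)
        out = auroc_ovr(scores, labels)
        assert out["macro"] == pytest.approx(50.0, abs=2.0)

    def test_matches_all_pairs_brute_force(self, rng):
        """Rank formula equals O(n^2) pair counting with half-credit ties."""
        n = 50
        scores = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
        outcomes = rng.integers(0, 2, n).astype(bool)
        pos, neg = scores[outcomes], scores[~outcomes]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = wins / (len(pos) * len(neg))
        full = np.zeros((n, 4))
        full[:, 0] = scores
        labels = np.where(outcomes, 0, 1)
        got = auroc_ovr(full, labels)["meningioma"] / 100
        assert got == pytest.approx(expected, abs=1e-6)

    def test_single_outcome_class_undefined(self, rng):
        scores = rng.dirichlet(np.ones(4), size=20)
        labels = np.repeat([0, 1], 10)  # classes 2 and 3 absent
        with pytest.warns(UserWarning):
            out = auroc_ovr(scores, labels)
        assert np.isnan(out["ependymoma"])


class TestClusterBootstrap:
    def _frame(self, rng, n_pat=30):
        rows = []
        for i in range(n_pat):
            truth = i % 4
            for s in range(int(rng.integers(1, 4))):
                pred = truth if rng.uniform() < 0.8 else int(rng.integers(0, 4))
                rows.append({"patient_id": f"P{i}", "y_true": truth, "y_pred": pred})
        return pd.DataFrame(rows)

    def test_constant_metric_gives_zero_width_ci(self, rng):
        frame = self._frame(rng)
        lo, hi = cluster_bootstrap_ci(lambda f: 42.0, frame, b=50, seed=1)
        assert lo == hi == 42.0

    def test_endpoints_within_percentage_range(self, rng):
        frame = self._frame(rng)
        lo, hi = cluster_bootstrap_ci(macro_balanced_accuracy, frame, b=200, seed=2)
        assert 0.0 <= lo <= hi <= 100.0

    def test_seed_determinism(self, rng):
        frame = self._frame(rng)
        a = cluster_bootstrap_ci(macro_balanced_accuracy, frame, b=100, seed=3)
        b = cluster_bootstrap_ci(macro_balanced_accuracy, frame, b=100, seed=3)
        assert a == b

    def test_requires_two_clusters(self):
        frame = pd.DataFrame({"patient_id": ["a"] * 3, "y_true": [0, 1, 2],
                              "y_pred": [0, 1, 2]})
        with pytest.raises(ValueError, match="clusters"):
            cluster_bootstrap_ci(macro_balanced_accuracy, frame, b=10)


class TestBrier:
    def test_perfect_onehot_is_zero(self):
        probs = np.eye(4)[[0, 1, 2, 3]]
        out = brier_scores(probs, np.arange(4))
        assert out["overall"] == 0.0

    def test_uniform_vs_onehot_is_three_quarters(self):
        probs = np.full((10, 4), 0.25)
        out = brier_scores(probs, np.zeros(10, dtype=int))
        assert out["overall"] == pytest.approx(0.75)  # 0.75^2 + 3 * 0.25^2

    def test_matches_elementwise_brute_force(self, rng):
        probs = rng.dirichlet(np.ones(4), size=200)
        labels = rng.integers(0, 4, 200)
        out = brier_scores(probs, labels)
        manual = np.mean([
            sum((probs[i, c] - (1.0 if labels[i] == c else 0.0)) ** 2
                for c in range(4))
            for i in range(200)])
        assert out["overall"] == pytest.approx(manual, abs=1e-12)
        manual_c0 = np.mean([(probs[i, 0] - (labels[i] == 0)) ** 2
                             for i in range(200)])
        assert out["meningioma"] == pytest.approx(manual_c0, abs=1e-12)


class TestECE:
    def test_all_certain_and_correct_is_zero(self):
        scores = np.ones(100)
        outcomes = np.ones(100)
        assert expected_calibration_error(scores, outcomes) == 0.0

    def test_perfectly_calibrated_fixture_near_zero(self):
        """With confidence == correctness rate, ECE vanishes at n = 10^5."""
        y, probs = make_probability_fixture(
            100_000, ReliabilityProfile.perfectly_calibrated(), seed=0)
        top = probs.max(axis=1)
        correct = (np.argmax(probs, axis=1) == y).astype(float)
        assert expected_calibration_error(top, correct) < 0.01

    def test_injected_miscalibration_recovered(self):
        """A uniform confidence-accuracy gap of delta shows up as ECE = delta."""
        delta = 0.1
        y, probs = make_probability_fixture(
            100_000, ReliabilityProfile.miscalibrated(delta), seed=1)
        top = probs.max(axis=1)
        correct = (np.argmax(probs, axis=1) == y).astype(float)
        assert expected_calibration_error(top, correct) == pytest.approx(
            delta, abs=0.01)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            expected_calibration_error(np.array([1.2]), np.array([1.0]))


class TestDecisionCurve:
    def test_treat_none_is_zero_and_treat_all_limit(self, rng):
        scores = rng.uniform(0, 1, 500)
        outcomes = rng.uniform(0, 1, 500) < 0.3
        curve = decision_curve(scores, outcomes, thresholds=[0.01, 0.5])
        assert np.all(curve["treat_none"] == 0.0)
        prev = outcomes.mean()
        assert curve["treat_all"].iloc[0] == pytest.approx(prev, abs=0.02)

    def test_matches_counting_oracle_on_20_cases(self):
        """Net benefit equals direct TP/FP counting at each threshold."""
        scores = np.array([0.95, 0.9, 0.85, 0.8, 0.75, 0.7, 0.65, 0.6, 0.55,
                           0.5, 0.45, 0.4, 0.35, 0.3, 0.25, 0.2, 0.15, 0.1,
                           0.05, 0.02])
        outcomes = np.array([1, 1, 1, 0, 1, 1, 0, 1, 0, 0,
                             1, 0, 0, 0, 1, 0, 0, 0, 0, 0], dtype=bool)
        thresholds = np.arange(0.1, 0.91, 0.1)
        curve = decision_curve(scores, outcomes, thresholds=thresholds)
        n = 20
        for _, row in curve.iterrows():
            pt = row["threshold"]
            tp = int(np.sum((scores >= pt) & outcomes))
            fp = int(np.sum((scores >= pt) & ~outcomes))
            expected = tp / n - fp / n * pt / (1 - pt)
            assert row["net_benefit"] == pytest.approx(expected, abs=1e-12)

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            decision_curve(np.array([0.5]), np.array([True]), thresholds=[1.0])


class TestPrevalenceAdjustment:
    def _scenario(self, pi0):
        prev = np.array([pi0, *(np.ones(3) * (1 - pi0) / 3)])
        return PrevalenceScenario("test", prev)

    def test_perfect_specificity_gives_unit_ppv(self):
        out = prevalence_adjusted_predictive_values(
            [0.8] * 4, [1.0] * 4, self._scenario(0.3))
        assert out["ppv"].iloc[0] == pytest.approx(1.0)

    def test_zero_prevalence_edge(self):
        scenario = PrevalenceScenario("edge", np.array([0.0, 0.5, 0.3, 0.2]))
        with pytest.warns(UserWarning, match="PPV undefined"):
            out = prevalence_adjusted_predictive_values(
                [0.9] * 4, [0.9] * 4, scenario)
        assert np.isnan(out["ppv"].iloc[0])
        assert out["npv"].iloc[0] == pytest.approx(1.0)

    def test_matches_monte_carlo_contingency(self, rng):
        """Bayes formulas agree with a 10^6-draw simulation within 0.003."""
        sens, spec, pi = 0.895, 0.915, 0.6
        n = 1_000_000
        disease = rng.uniform(size=n) < pi
        positive = np.where(disease, rng.uniform(size=n) < sens,
                            rng.uniform(size=n) < (1 - spec))
        mc_ppv = disease[positive].mean()
        mc_npv = (~disease[~positive]).mean()
        out = prevalence_adjusted_predictive_values(
            [sens] * 4, [spec] * 4, self._scenario(pi))
        assert out["ppv"].iloc[0] == pytest.approx(mc_ppv, abs=0.003)
        assert out["npv"].iloc[0] == pytest.approx(mc_npv, abs=0.003)


class _FakeSlide:
    def __init__(self, pred, n=10, conf=0.9):
        self.prediction = pred
        self.n_patches = n
        self.confidence = conf
        self.slide_id = "s"

    def _active(self):
        p = np.full(4, (1 - self.confidence) / 3)
        p[self.prediction] = self.confidence
        return p


class _FakePatient:
    def __init__(self, pid, truth, slide_preds, n=10, conf=0.9):
        self.patient_id = pid
        self.truth = truth
        self.slides = [_FakeSlide(p, n, conf) for p in slide_preds]
        self.strata = {}
        self.n_patches = sum(s.n_patches for s in self.slides)
        self.tau_conf = None

    @property
    def prediction(self):
        vals, counts = np.unique([s.prediction for s in self.slides],
                                 return_counts=True)
        return int(vals[np.argmax(counts)])

    @property
    def correct(self):
        return self.prediction == self.truth

    @property
    def confidence(self):
        return float(np.mean([s.confidence for s in self.slides]))

    @property
    def probs(self):
        return np.mean([s._active() for s in self.slides], axis=0)


class TestOneRandomSlide:
    def test_single_slide_patients_have_zero_variance(self):
        pats = [_FakePatient(f"P{i}", i % 4, [i % 4]) for i in range(8)]
        out = one_random_slide_eval(pats, repetitions=20, seed=0)
        assert out["sd"] == 0.0
        assert out["mean"] == pytest.approx(100.0)

    def test_fixed_seed_reproducible(self):
        pats = [_FakePatient(f"P{i}", i % 4, [i % 4, (i + 1) % 4])
                for i in range(12)]
        a = one_random_slide_eval(pats, repetitions=5, seed=3)
        b = one_random_slide_eval(pats, repetitions=5, seed=3)
        assert np.array_equal(a["values"], b["values"])

    def test_identical_slides_match_full_cohort_value(self):
        """If all of a patient's slides agree, subsampling changes nothing."""
        pats = [_FakePatient(f"P{i}", i % 4, [(i + 1) % 4] * 3)
                for i in range(16)]
        out = one_random_slide_eval(pats, repetitions=10, seed=1)
        frame = pd.DataFrame({"patient_id": [p.patient_id for p in pats],
                              "y_true": [p.truth for p in pats],
                              "y_pred": [p.prediction for p in pats]})
        assert out["mean"] == pytest.approx(macro_balanced_accuracy(frame))
        assert out["sd"] == pytest.approx(0.0, abs=1e-12)


class TestPatchCountAnalysis:
    def test_odds_ratio_percent_identity(self):
        from spinesrh.evalstats import odds_ratio_to_percent

        assert odds_ratio_to_percent(1.00533) == pytest.approx(0.533)

    def test_null_case_identical_counts(self, rng):
        pats = [_FakePatient(f"P{i}", i % 4, [i % 4 if i < 20 else (i + 1) % 4],
                             n=15) for i in range(30)]
        with pytest.warns(UserWarning):
            out = patch_count_analysis(pats)
        assert out["mannwhitney_p"] > 0.9
        assert out["mean_correct"] == out["mean_incorrect"] == 15.0

    def test_planted_logistic_coefficient_recovered(self, rng):
        """OR from a planted per-patch log-odds slope lands inside its CI."""
        beta, n = 0.005, 500
        counts = rng.integers(20, 400, n)
        logit = -0.5 + beta * counts
        correct = rng.uniform(size=n) < 1 / (1 + np.exp(-logit))
        pats = []
        for i in range(n):
            truth = i % 4
            pred = truth if correct[i] else (truth + 1) % 4
            pats.append(_FakePatient(f"P{i}", truth, [pred], n=int(counts[i])))
        out = patch_count_analysis(pats)
        lo, hi = out["or_ci"]
        assert lo <= np.exp(beta) <= hi
        assert out["odds_ratio"] == pytest.approx(np.exp(beta), abs=0.004)


class TestAblation:
    def _frame(self, preds, truths):
        return pd.DataFrame({"patient_id": [f"P{i}" for i in range(len(preds))],
                             "y_true": truths, "y_pred": preds})

    def test_identical_reports_give_zero_differences(self, rng):
        truths = np.arange(16) % 4
        preds = truths.copy()
        out = ablation_compare(self._frame(preds, truths),
                               self._frame(preds, truths), b=0)
        assert out["macro_difference"] == 0.0
        assert all(v == 0.0 for v in out["per_class_difference"].values())

    def test_macro_difference_equals_macro_of_per_class_differences(self, rng):
        truths = np.arange(40) % 4
        p1 = np.where(rng.uniform(size=40) < 0.9, truths, (truths + 1) % 4)
        p2 = np.where(rng.uniform(size=40) < 0.7, truths, (truths + 2) % 4)
        out = ablation_compare(self._frame(p1, truths), self._frame(p2, truths),
                               b=0)
        per_class_mean = np.mean(list(out["per_class_difference"].values()))
        assert out["macro_difference"] == pytest.approx(per_class_mean, abs=1e-10)
        assert out["macro_difference"] == pytest.approx(
            out["macro_transformer"] - out["macro_linear"], abs=1e-10)

    def test_cohort_mismatch_rejected(self):
        a = self._frame([0, 1], [0, 1])
        b = self._frame([0, 1, 2], [0, 1, 2])
        with pytest.raises(ValueError, match="identical patient"):
            ablation_compare(a, b)


def test_stratified_reports_recombine_to_pooled_confusion(rng):
    rows = []
    for i in range(60):
        truth = i % 4
        pred = truth if rng.uniform() < 0.8 else int(rng.integers(0, 4))
        rows.append({"patient_id": f"P{i}", "y_true": truth, "y_pred": pred,
                     "site": ["NYU", "UM", "MUV"][i % 3],
                     **{f"p_{c}": 0.25 for c in CLASSES}})
    frame = pd.DataFrame(rows)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        subs = stratified_reports(frame, "site", b=0, with_dca=False)
        pooled = compute_metrics_report(frame, b=0, with_dca=False)
    # per-class TP counts recombine exactly across strata
    for c, name in enumerate(CLASSES):
        pooled_tp = np.sum((frame.y_true == c) & (frame.y_pred == c))
        strat_tp = sum(np.sum((g.y_true == c) & (g.y_pred == c))
                       for _, g in frame.groupby("site"))
        assert pooled_tp == strat_tp
    assert set(subs) == {"NYU", "UM", "MUV"}
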