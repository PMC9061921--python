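import numpy as np
import pandas as pd
import pytest

import oracles
from rectomics.evaluate import (
    ConfusionCounts,
    compare_models,
    confusion,
    error_analysis,
    mann_whitney,
    metrics,
    roc_auc,
    round_half_away,
    select_best,
    validate,
)


class TestConfusion:
    def test_all_correct(self):
        c = confusion(np.array([1, 0, 1]), np.array([1, 0, 1]))
        assert (c.fp, c.fn) == (0, 0)

    def test_all_wrong(self):
        c = confusion(np.array([0, 1]), np.array([1, 0]))
        assert (c.tp, c.tn) == (0, 0)

    def test_external_validation_counts(self):
        # 15 responders of whom 9 predicted responder; 13 nonresponders of
        # whom 10 predicted nonresponder
        labels = np.array([1] * 15 + [0] * 13)
        preds = np.array([1] * 9 + [0] * 6 + [0] * 10 + [1] * 3)
        c = confusion(preds, labels)
        assert (c.tp, c.fn, c.tn, c.fp) == (9, 6, 10, 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.array([1]), np.array([1, 0]))


class TestMetrics:
    def test_manual_model_validation_row(self):
        """TP=9 FN=6 TN=10 FP=3: ACC 68, SE 60, SP 77, NPV 63, PPV 75."""
        r = metrics(ConfusionCounts(tp=9, fn=6, tn=10, fp=3))
        assert r.accuracy.percent == 68 and r.accuracy.rate == "19/28"
        assert r.sensitivity.percent == 60 and r.sensitivity.rate == "9/15"
        assert r.specificity.percent == 77 and r.specificity.rate == "10/13"
        assert r.npv.percent == 63 and r.npv.rate == "10/16"
        assert r.ppv.percent == 75 and r.ppv.rate == "9/12"

    def test_automatic_model_validation_row(self):
        """TP=12 FN=3 TN=9 FP=4: ACC 75, SE 80, SP 69, NPV 75, PPV 75."""
        r = metrics(ConfusionCounts(tp=12, fn=3, tn=9, fp=4))
        assert (r.accuracy.percent, r.sensitivity.percent, r.specificity.percent,
                r.npv.percent, r.ppv.percent) == (75, 80, 69, 75, 75)

    def test_perfect_classifier(self):
        r = metrics(ConfusionCounts(tp=50, fn=0, tn=50, fp=0))
        assert all(
            m.percent == 100
            for m in (r.accuracy, r.sensitivity, r.specificity, r.npv, r.ppv)
        )

    def test_zero_denominator_is_undefined_not_zero(self):
        r = metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=1))
        assert r.sensitivity is None and r.accuracy is not None

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(62.5) == 63
        assert round_half_away(67.5) == 68
        assert round_half_away(-0.5) == -1

    def test_confidence_intervals_contain_point_estimate(self):
        r = metrics(ConfusionCounts(tp=9, fn=6, tn=10, fp=3))
        for m in (r.accuracy, r.sensitivity, r.specificity, r.npv, r.ppv):
            lo, hi = m.ci_percent
            assert lo <= m.percent <= hi


class TestRocAuc:
    def test_perfect_and_reversed_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y)[0] == 1.0
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), y)[0] == 0.0

    def test_pair_counting_example(self):
        auc, ci = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)
        assert ci[0] <= auc <= ci[1]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(8, 24))
            scores = rng.random(n).round(1)  # ties likely
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            assert roc_auc(scores, y, n_boot=10)[0] == pytest.approx(
                oracles.pairwise_auc(scores, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class _FakeModel:
    def __init__(self, n_features, name="m"):
        self.n_features = n_features
        self.spec = type("S", (), {"describe": staticmethod(lambda: name)})()


def _report(acc_num, acc_den, ppv_num, ppv_den, auc):
    from rectomics.evaluate import MetricValue, PerformanceReport

    return PerformanceReport(
        accuracy=MetricValue(acc_num, acc_den), sensitivity=None, specificity=None,
        npv=None, ppv=MetricValue(ppv_num, ppv_den), auc=auc,
    )


class TestSelectBest:
    def test_overfit_candidate_excluded_despite_higher_accuracy(self):
        overfit = (_FakeModel(30), _report(66, 67, 39, 40, 1.00))
        honest = (_FakeModel(30), _report(55, 67, 23, 31, 0.90))
        best, report, exclusions = select_best([overfit, honest])
        assert report.auc == 0.90
        assert len(exclusions) == 1 and "overfitting" in exclusions[0]["reason"]

    def test_auc_exactly_099_is_excluded(self):
        borderline = (_FakeModel(10), _report(63, 67, 37, 40, 0.99))
        keeper = (_FakeModel(10), _report(54, 67, 25, 36, 0.87))
        best, report, exclusions = select_best([borderline, keeper])
        assert report.auc == 0.87

    def test_ppv_breaks_accuracy_ties(self):
        a = (_FakeModel(10, "a"), _report(55, 67, 74, 100, 0.90))
        b = (_FakeModel(10, "b"), _report(55, 67, 70, 100, 0.88))
        best, report, _ = select_best([a, b])
        assert report.ppv.percent == 74

    def test_fewer_features_break_remaining_ties(self):
        a = (_FakeModel(30, "a"), _report(55, 67, 74, 100, 0.90))
        b = (_FakeModel(10, "b"), _report(55, 67, 74, 100, 0.90))
        best, _, _ = select_best([a, b])
        assert best.n_features == 10

    def test_single_eligible_candidate(self):
        only = (_FakeModel(5), _report(50, 67, 20, 30, 0.8))
        best, _, _ = select_best([only])
        assert best.n_features == 5

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="excluded"):
            select_best([(_FakeModel(5), _report(66, 67, 39, 40, 1.0))])


class TestValidateGuards:
    def test_refuses_construction_rows(self):
        with pytest.raises(ValueError, match="leakage"):
            validate(object(), pd.DataFrame({"split": []}), split="construction-train")

    def test_missing_split_rows(self):
        model = _FakeModel(1)
        model.normalization = None
        with pytest.raises(ValueError, match="no rows"):
            validate(model, pd.DataFrame({"split": ["construction-train"]}))


class TestMannWhitney:
    def test_exact_small_sample_example(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_exact_enumeration_for_small_groups(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            n1, n2 = rng.integers(3, 7, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert mann_whitney(x, y) == pytest.approx(
                oracles.exact_mannwhitney_p(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def _per_case(ids, labels, preds):
    frame = pd.DataFrame({"id": ids, "label": labels, "prediction": preds})
    frame["correct"] = frame["label"] == frame["prediction"]
    return frame


class TestErrorAnalysis:
    def test_identical_predictions_make_both_sets_equal(self):
        ids = [f"c{i}" for i in range(8)]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        preds = [1, 0, 1, 0, 0, 1, 0, 0]
        rep = error_analysis(
            _per_case(ids, labels, preds), _per_case(ids, labels, preds),
            dsc_by_case={i: 0.8 for i in ids}, volume_by_case={i: 10.0 for i in ids},
        )
        assert rep.n_misclassified_manual == rep.n_misclassified_automatic == 3
        assert rep.n_misclassified_both == 3

    def test_empty_group_reports_not_applicable(self):
        ids = ["a", "b"]
        rep = error_analysis(
            _per_case(ids, [1, 0], [1, 0]), _per_case(ids, [1, 0], [1, 0]),
            {i: 0.9 for i in ids}, {i: 5.0 for i in ids},
        )
        assert rep.pvalues["volume_correct_vs_misclassified_manual"] is None


class TestCompareModels:
    def test_identical_predictions_give_mcnemar_one(self):
        y = np.array([1, 0, 1, 0, 1])
        p = np.array([1, 0, 0, 0, 1])
        out = compare_models(p, p, y)
        assert out["mcnemar_p"] == 1.0

    def test_total_disagreement_exact_binomial(self):
        y = np.ones(20, dtype=int)
        a = y.copy()           # all correct
        b = np.zeros(20, int)  # all wrong
        out = compare_models(a, b, y)
        assert out["mcnemar_p"] == pytest.approx(2.0 ** -19)
        assert out["discordant"] == {"a_only_correct": 20, "b_only_correct": 0}

    def test_two_proportion_p_shrinks_with_wider_gap(self):
        y = np.array([1] * 15 + [0] * 15)

        def preds(se_hits):
            p = np.concatenate([np.ones(se_hits), np.zeros(15 - se_hits), np.zeros(15)])
            return p.astype(int)

        base = compare_models(preds(12), preds(9), y)["two_proportion"]["se"]
        wide = compare_models(preds(14), preds(5), y)["two_proportion"]["se"]
        assert wide < base
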