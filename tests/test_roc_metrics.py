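import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ssmpca.roc_metrics import (
    classify,
    concordance_combine,
    confusion_counts,
    predictive_values,
    roc_curve,
    roc_report,
    youden_threshold,
)

REF, TGT = "reference", "target"


def _pair_count_auc(scores, labels):
    """Oracle: explicit enumeration of (target, reference) pairs, ties = 1/2."""
    y = np.asarray(labels, dtype=object) == TGT
    pos = np.asarray(scores, dtype=float)[y]
    neg = np.asarray(scores, dtype=float)[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([1, 2, 3, 4], [REF, REF, TGT, TGT], 1.0),
            ([1, 2, 3, 4], [TGT, TGT, REF, REF], 0.0),
            ([1, 2, 2, 3], [REF, TGT, REF, TGT], 0.875),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert roc_curve(np.array(scores, float), np.array(labels, object)).auc == pytest.approx(
            expected
        )

    def test_matches_pair_enumeration_and_sklearn_on_random_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            labels = np.array([REF, TGT] * 10, dtype=object)[:n]
            rng.shuffle(labels)
            if len(set(labels)) < 2:
                labels[0], labels[1] = REF, TGT
            scores = rng.integers(0, 6, size=n).astype(float)  # integer scores force ties
            auc = roc_curve(scores, labels).auc
            assert auc == pytest.approx(_pair_count_auc(scores, labels), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels == TGT, scores), abs=1e-12)

    def test_negated_scores_complement_auc(self, rng):
        scores = rng.normal(size=20)
        labels = np.array([REF] * 10 + [TGT] * 10, dtype=object)
        assert roc_curve(scores, labels).auc + roc_curve(-scores, labels).auc == pytest.approx(1.0)

    def test_invariant_under_strictly_monotone_transforms(self, rng):
        scores = rng.normal(size=16)
        labels = np.array([REF, TGT] * 8, dtype=object)
        base = roc_curve(scores, labels).auc
        for f in (np.exp, lambda x: 3 * x + 1, lambda x: x**3 + x):
            assert roc_curve(f(scores), labels).auc == pytest.approx(base, abs=1e-12)

    def test_pair_counting_equals_trapezoidal_area(self, rng):
        scores = rng.integers(0, 4, size=18).astype(float)
        labels = np.array([REF, TGT] * 9, dtype=object)
        roc = roc_curve(scores, labels)
        # points are in ascending-threshold order, i.e. the ROC polyline
        # traversed from (1, 1) down to (0, 0)
        fpr = np.array([1.0 - p.specificity for p in roc.points])
        tpr = np.array([p.sensitivity for p in roc.points])
        area = -np.trapezoid(tpr, fpr)
        assert roc.auc == pytest.approx(area, abs=1e-9)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.arange(4.0), np.array([REF] * 4, dtype=object))


class TestYouden:
    def test_perfect_separation_gives_full_J(self):
        labels = np.array([REF] * 3 + [TGT] * 3, dtype=object)
        roc = roc_curve(np.array([1.0, 2, 3, 10, 11, 12]), labels)
        t, sens, spec = youden_threshold(roc)
        assert sens == 1.0 and spec == 1.0
        report = roc_report(np.array([1.0, 2, 3, 10, 11, 12]), labels)
        assert report.sensitivity == 100.0 and report.specificity == 100.0

    def test_identical_scores_are_degenerate_with_zero_J(self):
        labels = np.array([REF, REF, TGT, TGT], dtype=object)
        report = roc_report(np.zeros(4), labels)
        assert report.degenerate
        t, sens, spec = youden_threshold(report)
        assert sens + spec - 1.0 == pytest.approx(0.0)

    def test_co_optimal_cuts_enumerated_and_tiebreak_prefers_specificity(self):
        """Scores 1..6, targets at 3, 5, 6: J = 2/3 at cuts 2 and 4 (verified
        by exhaustive sweep); the tie-break returns the higher-specificity cut."""
        scores = np.arange(1.0, 7.0)
        labels = np.array([REF, REF, TGT, REF, TGT, TGT], dtype=object)
        roc = roc_curve(scores, labels)
        # oracle: exhaustive sweep over all thresholds
        best_j = max(p.sensitivity + p.specificity - 1.0 for p in roc.points)
        optima = {
            p.threshold
            for p in roc.points
            if p.sensitivity + p.specificity - 1.0 == pytest.approx(best_j)
        }
        assert optima == {2.0, 4.0}
        all_points = youden_threshold(roc, return_all=True)
        assert {t for t, _, _ in all_points} == {2.0, 4.0}
        t, sens, spec = youden_threshold(roc)
        assert t == 4.0 and spec == 1.0


class TestPredictiveValues:
    @pytest.mark.parametrize(
        "confusion, expected",
        [
            ((10, 2, 13, 5), (83, 72)),
            ((14, 7, 8, 1), (67, 89)),
            ((13, 6, 9, 2), (68, 82)),
        ],
    )
    def test_confusion_matrix_arithmetic(self, confusion, expected):
        assert predictive_values(*confusion) == expected

    def test_empty_denominator_is_flagged_not_zero(self):
        ppv, npv = predictive_values(0, 0, 5, 5)
        assert ppv is None and npv == 50
        with pytest.raises(ValueError, match="negative"):
            predictive_values(-1, 0, 0, 0)


class TestClassify:
    def test_all_below_threshold_are_reference(self):
        assert list(classify(np.array([0.1, 0.5]), 1.0)) == [REF, REF]

    def test_boundary_score_is_reference(self):
        assert classify(np.array([1.0, 1.0 + 1e-9]), 1.0).tolist() == [REF, TGT]

    def test_nonfinite_threshold_is_error(self):
        with pytest.raises(ValueError, match="finite"):
            classify(np.zeros(2), np.inf)

    def test_report_metrics_match_reclassification(self, rng):
        scores = rng.normal(size=20)
        labels = np.array([REF, TGT] * 10, dtype=object)
        report = roc_report(scores, labels)
        pred = classify(scores, report.youden_threshold)
        tp, fp, tn, fn = confusion_counts(pred, labels)
        assert report.confusion == (tp, fp, tn, fn)
        assert report.sensitivity == pytest.approx(100.0 * tp / (tp + fn))
        assert report.specificity == pytest.approx(100.0 * tn / (tn + fp))
        assert sum(report.confusion) == 20


class TestConcordance:
    def test_full_agreement_reproduces_single_modality_metrics(self):
        pred = np.array([TGT, REF, TGT, REF], dtype=object)
        truth = np.array([TGT, REF, REF, REF], dtype=object)
        rep = concordance_combine(pred, pred.copy(), truth)
        assert rep.concordance_percent == 100.0
        assert rep.confusion == confusion_counts(pred, truth)

    def test_complete_disagreement_yields_empty_subset(self):
        a = np.array([TGT, REF], dtype=object)
        b = np.array([REF, TGT], dtype=object)
        rep = concordance_combine(a, b, a)
        assert rep.concordance_percent == 0.0
        assert rep.empty_subset and rep.confusion is None

    def test_hand_tallied_partial_agreement(self):
        """10 subjects, agreement on 6 by construction; confusion within the
        concordant subset matches a hand tally (TP=2, FP=1, TN=2, FN=1)."""
        a = np.array([TGT, TGT, REF, REF, TGT, REF, TGT, REF, TGT, REF], dtype=object)
        b = np.array([TGT, TGT, REF, REF, TGT, REF, REF, TGT, REF, TGT], dtype=object)
        truth = np.array([TGT, REF, REF, TGT, TGT, REF, TGT, REF, TGT, REF], dtype=object)
        rep = concordance_combine(a, b, truth)
        assert rep.concordance_percent == pytest.approx(60.0)
        assert rep.concordant_ids == [0, 1, 2, 3, 4, 5]
        assert rep.confusion == (2, 1, 2, 1)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length"):
            concordance_combine(np.array([TGT]), np.array([TGT, REF]), np.array([TGT, REF]))
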