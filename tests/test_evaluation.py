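"""Dice/Hausdorff, ROC/AUC, confusion metrics, thresholds, cohort aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrgart.evaluation import (
    aggregate_cohort,
    confusion_at_threshold,
    dice,
    hausdorff,
    roc_auc,
    select_threshold,
)


def brute_force_auc(labels, probs):
    """O(n^2) Mann-Whitney concordance with ties counted 1/2."""
    pos = [p for y, p in zip(labels, probs) if y == 1]
    neg = [p for y, p in zip(labels, probs) if y == 0]
    s = 0.0
    for pp in pos:
        for pn in neg:
            s += 1.0 if pp > pn else (0.5 if pp == pn else 0.0)
    return s / (len(pos) * len(neg))


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5, 5)); m[1:4, 1:4, 1:4] = 1
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5, 5)); a[0, 0, 0] = 1
        b = np.zeros((5, 5, 5)); b[4, 4, 4] = 1
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4)); b = np.zeros((4, 4, 4))
        a.ravel()[:8] = 1
        b.ravel()[4:12] = 1  # |a|=|b|=8, 4 shared
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3, 3))
        assert dice(z, z) == 1.0

    def test_symmetry_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        a = (rng.random((6, 6, 6)) > 0.6).astype(float)
        b = (rng.random((6, 6, 6)) > 0.6).astype(float)
        assert dice(a, b) == dice(b, a)
        assert dice(np.roll(a, 1, 0), np.roll(b, 1, 0)) == pytest.approx(dice(a, b))


class TestHausdorff:
    def test_identical_is_zero(self):
        m = np.zeros((6, 6, 6)); m[2:5, 2:5, 2:5] = 1
        assert hausdorff(m, m) == 0.0

    def test_single_voxels_five_apart(self):
        a = np.zeros((8, 8, 8)); a[1, 1, 1] = 1
        b = np.zeros((8, 8, 8)); b[6, 1, 1] = 1
        assert hausdorff(a, b, spacing=(1, 1, 1)) == pytest.approx(5.0)

    def test_anisotropic_spacing_one_slice_apart(self):
        a = np.zeros((4, 4, 4)); a[1, 1, 1] = 1
        b = np.zeros((4, 4, 4)); b[1, 1, 2] = 1
        assert hausdorff(a, b, spacing=(1, 1, 3)) == pytest.approx(3.0)

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a = (rng.random((7, 7, 7)) > 0.7).astype(float); a[3, 3, 3] = 1
        b = (rng.random((7, 7, 7)) > 0.7).astype(float); b[2, 2, 2] = 1
        assert hausdorff(a, b) == hausdorff(b, a)

    def test_empty_mask_raises(self):
        m = np.zeros((4, 4, 4)); m[1, 1, 1] = 1
        with pytest.raises(ValueError):
            hausdorff(m, np.zeros((4, 4, 4)))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_reversed_ranking(self):
        auc, _ = roc_auc([1, 0], [0.4, 0.6])
        assert auc == 0.0

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            y = rng.integers(0, 2, size=20)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = np.round(rng.random(20), 2)  # rounding forces ties
            auc, _ = roc_auc(y, p)
            assert auc == pytest.approx(brute_force_auc(y, p), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        p = rng.random(50)
        assert roc_auc(y, p)[0] == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        p = rng.random(20)
        base = roc_auc(y, p)[0]
        for f in (lambda x: x**3, lambda x: np.exp(2 * x), lambda x: 1 / (1 + np.exp(-5 * x))):
            assert roc_auc(y, f(p))[0] == pytest.approx(base, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.2, 0.4, 0.6])


class TestConfusion:
    def test_worked_counts(self):
        # TP=2, FP=1, FN=1, TN=6 at threshold 0.5
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        p = [0.9, 0.8, 0.2, 0.7, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        counts, m = confusion_at_threshold(y, p, 0.5)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (2, 1, 1, 6)
        assert m.f1 == pytest.approx(4 / 6)
        assert m.accuracy == pytest.approx(0.8)

    def test_all_correct(self):
        _, m = confusion_at_threshold([0, 1], [0.1, 0.9], 0.5)
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_strict_threshold_rule(self):
        counts, _ = confusion_at_threshold([1], [0.64], 0.64)
        assert counts.fn == 1  # p == threshold predicts ATP

    def test_degenerate_sensitivity_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            _, m = confusion_at_threshold([0, 0], [0.1, 0.2], 0.5)
        assert math.isnan(m.sensitivity)

    def test_accuracy_is_prevalence_weighted_sen_spec(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        p = rng.random(40)
        _, m = confusion_at_threshold(y, p, 0.5)
        prev = y.mean()
        assert m.accuracy == pytest.approx(prev * m.sensitivity + (1 - prev) * m.specificity)


class TestSelectThreshold:
    def test_separated_classes_threshold_between(self):
        y = [0, 0, 0, 1, 1, 1]
        p = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        for crit in ("youden", "balance"):
            thr = select_threshold(y, p, crit)
            assert 0.3 < thr < 0.7

    def test_balance_near_symmetric_midpoint(self):
        y = [0] * 5 + [1] * 5
        p = [0.1, 0.2, 0.3, 0.4, 0.45, 0.55, 0.6, 0.7, 0.8, 0.9]
        thr = select_threshold(y, p, "balance")
        _, m = confusion_at_threshold(y, p, thr)
        assert m.sensitivity == pytest.approx(m.specificity)
        assert 0.45 < thr < 0.55

    def test_self_consistency_of_returned_threshold(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.zeros(12, int), np.ones(12, int)]
        p = np.clip(rng.normal(0.4 + 0.25 * y, 0.15), 0, 1)
        thr = select_threshold(y, p, "youden")
        _, m = confusion_at_threshold(y, p, thr)
        # no other candidate threshold has a larger Youden index
        others = [
            confusion_at_threshold(y, p, t)[1]
            for t in np.linspace(0, 1, 101)
        ]
        best = max(o.sensitivity + o.specificity - 1 for o in others if not math.isnan(o.sensitivity))
        assert m.sensitivity + m.specificity - 1 >= best - 1e-12


class TestAggregateCohort:
    def test_clinical_cohort_totals(self):
        rows = [(0, 5)] * 17 + [(1, 4)] * 9 + [(2, 3)] * 4 + [(3, 2)] * 2 + [(4, 1)] * 1 + [(5, 0)] * 3
        s = aggregate_cohort(rows)
        assert s.total == 180
        assert (s.total_atp, s.total_ats) == (42, 138)
        assert (s.percent_atp, s.percent_ats) == (23, 77)

    def test_single_patient(self):
        s = aggregate_cohort([(0, 5)])
        assert (s.percent_atp, s.percent_ats) == (0, 100)

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError):
            aggregate_cohort([(0, 0), (0, 0)])

    def test_proportions_sum_to_one(self):
        s = aggregate_cohort([(2, 3), (1, 4)])
        assert s.proportion_atp + s.proportion_ats == pytest.approx(1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 9)), min_size=1, max_size=40))
def test_aggregate_totals_equal_sums(rows):
    if sum(a + s for a, s in rows) == 0:
        rows = rows + [(1, 1)]
    s = aggregate_cohort(rows)
    assert s.total_atp == sum(a for a, _ in rows)
    assert s.total_ats == sum(b for _, b in rows)
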