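"""Point metrics, macro averaging, ROC and the split construction."""

import numpy as np
import pytest

from lungtex.evaluation import (ConfusionMatrix, MetricError, ROCError,
                                SplitError, confusion, macro_roc, make_split,
                                metrics_from_confusion, metrics_from_rates)
from lungtex.published import COHORT_CLASS_COUNTS, REFERENCE_CLASS_METRICS
from lungtex.tissue import TissueClass
from lungtex.volume import AnnotatedPoint


def _points_from_counts(counts, n_subjects=40, seed=0):
    rng = np.random.default_rng(seed)
    pts = []
    for cls, n in counts.items():
        for i in range(n):
            subj = f"p{rng.integers(n_subjects):03d}"
            pts.append(AnnotatedPoint(scan_id=subj + "_scan",
                                      coord=(30, 30, 30), label=cls,
                                      subject_id=subj))
    return pts


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = np.repeat(np.arange(8), 3)
        cm = confusion(y, y)
        assert np.all(cm.counts == np.diag(np.full(8, 3)))

    def test_single_predicted_class_single_column(self):
        y = np.repeat(np.arange(8), 2)
        cm = confusion(y, np.zeros_like(y))
        assert cm.counts[:, 0].sum() == len(y)
        assert cm.counts[:, 1:].sum() == 0

    def test_three_sample_counting(self):
        cm = confusion([TissueClass.NP, TissueClass.GG, TissueClass.GG],
                       [TissueClass.NP, TissueClass.NP, TissueClass.GG])
        assert cm.counts[0, 0] == 1
        assert cm.counts[1, 0] == 1
        assert cm.counts[1, 1] == 1
        assert cm.counts.sum() == 3

    def test_row_sums_equal_class_counts_and_normalized_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 8, 300)
        p = rng.integers(0, 8, 300)
        cm = confusion(y, p)
        np.testing.assert_array_equal(cm.counts.sum(axis=1),
                                      np.bincount(y, minlength=8))
        norm = cm.normalized()
        np.testing.assert_allclose(norm.sum(axis=1), 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestMetrics:
    @pytest.mark.parametrize("cls", list(TissueClass))
    def test_published_per_class_rates_reproduce_printed_gm_and_ba(self, cls):
        ref = REFERENCE_CLASS_METRICS[cls]
        out = metrics_from_rates(ref["SN"], ref["SP"])
        assert out["GM"] == pytest.approx(ref["GM"], abs=1e-4)
        assert out["BA"] == pytest.approx(ref["BA"], abs=1e-4)

    def test_perfect_rates(self):
        out = metrics_from_rates(1.0, 1.0)
        assert out["GM"] == out["BA"] == 1.0

    def test_agrees_with_brute_force_tally(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 8, 1000)
        p = rng.integers(0, 8, 1000)
        m = metrics_from_confusion(confusion(y, p))
        for c in TissueClass:
            tp = np.sum((y == c) & (p == c))
            fn = np.sum((y == c) & (p != c))
            fp = np.sum((y != c) & (p == c))
            tn = np.sum((y != c) & (p != c))
            assert m.per_class[c]["SN"] == pytest.approx(tp / (tp + fn))
            assert m.per_class[c]["SP"] == pytest.approx(tn / (tn + fp))
            assert m.per_class[c]["GM"] == pytest.approx(
                np.sqrt(m.per_class[c]["SN"] * m.per_class[c]["SP"]))
            assert m.per_class[c]["BA"] == pytest.approx(
                (m.per_class[c]["SN"] + m.per_class[c]["SP"]) / 2)

    def test_macro_is_unweighted_mean_and_order_invariant(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 8, 400)
        p = rng.integers(0, 8, 400)
        m = metrics_from_confusion(confusion(y, p))
        assert m.macro["BA"] == pytest.approx(
            np.mean([m.per_class[c]["BA"] for c in TissueClass]))
        # relabelling classes by a permutation leaves the macro unchanged
        perm = rng.permutation(8)
        m2 = metrics_from_confusion(confusion(perm[y], perm[p]))
        assert m2.macro["BA"] == pytest.approx(m.macro["BA"])
        assert m2.macro["GM"] == pytest.approx(m.macro["GM"])

    def test_empty_class_raises_naming_it(self):
        y = np.zeros(10, int)   # only NP present: every other row is empty
        with pytest.raises(MetricError, match="NP|GG"):
            metrics_from_confusion(confusion(y, y))
        # a class with no true samples is named even when others are fine
        y2 = np.repeat(np.arange(7), 3)   # CL absent
        with pytest.raises(MetricError, match="CL"):
            metrics_from_confusion(confusion(y2, y2))

    def test_restricted_class_list_allows_toys(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0, 1, 1, 1])
        m = metrics_from_confusion(confusion(y, p),
                                   classes=[TissueClass.NP, TissueClass.GG])
        assert m.per_class[TissueClass.NP]["SN"] == pytest.approx(0.5)


class TestMacroRoc:
    def test_perfect_separation_gives_auc_1(self):
        n = 40
        labels = np.repeat([0, 1], n // 2)
        scores = np.zeros((n, 8))
        scores[np.arange(n), labels] = 1.0
        _, _, auc = macro_roc(scores, labels)
        assert auc == pytest.approx(1.0, abs=1e-9)

    def test_label_independent_scores_give_half(self):
        rng = np.random.default_rng(3)
        n = 4000
        labels = rng.integers(0, 4, n)
        scores = rng.dirichlet(np.ones(8), size=n)  # independent of labels
        _, _, auc = macro_roc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ROCError):
            macro_roc(np.ones((10, 8)), np.zeros(10))

    def test_macro_of_identical_curves_equals_common_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        n = 600
        labels = rng.integers(0, 2, n)
        s = rng.uniform(0, 1, n) * 0.5 + labels * 0.4
        scores = np.zeros((n, 8))
        scores[:, 0] = np.where(labels == 0, s, 1 - s)
        scores[:, 1] = np.where(labels == 1, s, 1 - s)
        grid, tpr, auc = macro_roc(scores, labels, fpr_grid=np.linspace(0, 1, 2001))
        per0 = roc_auc_score(labels == 0, scores[:, 0] / scores.sum(1))
        assert auc == pytest.approx(per0, abs=5e-3)


class TestMakeSplit:
    @pytest.fixture(scope="class")
    def cohort_points(self):
        return _points_from_counts(COHORT_CLASS_COUNTS, seed=5)

    def test_cohort_skew_reproduces_published_allocation(self, cohort_points):
        plan = make_split(cohort_points, rng_seed=0)
        assert len(plan.train_points(TissueClass.RETIC)) == 600
        assert len(plan.test_points(TissueClass.RETIC)) == 4809
        assert plan.roster_total() == 4800
        expected_test = {TissueClass.NP: 23096, TissueClass.GG: 34,
                         TissueClass.LINSC: 48, TissueClass.SUBPL: 103,
                         TissueClass.PS: 3245, TissueClass.CL: 3013}
        for cls, n in expected_test.items():
            assert len(plan.test_points(cls)) == n

    def test_small_class_rounding_up(self, cohort_points):
        plan = make_split(cohort_points, rng_seed=0)
        # 195 linear-scar points: ceil(0.75 * 195) = 147 train, 48 test
        assert len(plan.train_points(TissueClass.LINSC)) == 147
        # 413 subpleural points: ceil(0.75 * 413) = 310 train, 103 test
        assert len(plan.train_points(TissueClass.SUBPL)) == 310
        assert plan.per_class[TissueClass.LINSC].needs_augmentation
        assert not plan.per_class[TissueClass.NP].needs_augmentation

    def test_train_and_test_disjoint_with_stratified_folds(self, cohort_points):
        plan = make_split(cohort_points, rng_seed=1)
        for cls in TissueClass:
            tr = {id(p) for p in plan.train_points(cls)}
            te = {id(p) for p in plan.test_points(cls)}
            assert not tr & te
            folds = plan.fold_of[cls]
            assert len(folds) == 600
            assert np.bincount(folds, minlength=10).tolist() == [60] * 10

    def test_deterministic_under_seed(self, cohort_points):
        p1 = make_split(cohort_points, rng_seed=9)
        p2 = make_split(cohort_points, rng_seed=9)
        for cls in TissueClass:
            assert p1.train_points(cls) == p2.train_points(cls)
            assert p1.test_points(cls) == p2.test_points(cls)
            np.testing.assert_array_equal(p1.fold_of[cls], p2.fold_of[cls])

    def test_subject_level_split_keeps_subjects_apart(self):
        counts = {c: 40 for c in TissueClass}
        pts = _points_from_counts(counts, n_subjects=12, seed=6)
        plan = make_split(pts, level="subject", rng_seed=2,
                          target=20, n_folds=5, n_test_subjects=3)
        test_subjects = set(plan.test_subjects)
        assert len(test_subjects) == 3
        for cls in TissueClass:
            assert {p.subject_id for p in plan.train_points(cls)}.isdisjoint(
                test_subjects)
            assert all(p.subject_id in test_subjects
                       for p in plan.test_points(cls))
        covered = {p.label for c in TissueClass for p in plan.test_points(c)}
        assert covered == set(TissueClass)

    def test_missing_class_rejected(self):
        pts = _points_from_counts({TissueClass.NP: 10}, seed=7)
        with pytest.raises(SplitError, match="GG"):
            make_split(pts)
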