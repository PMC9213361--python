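"""Confusion tables, diagnostic metrics, ROC/AUC and cutoff selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lapchole import (
    ConfusionCounts,
    DegenerateInputError,
    GroupedCounts,
    ValidationError,
    auc_confidence_interval,
    auc_grouped,
    confusion_at_cutoff,
    cutoff_table,
    metrics_from_counts,
    roc_curve,
    youden_optimal_cutoff,
)
from lapchole.formatting import trunc2


def pair_counting_auc(scores, labels):
    """Brute-force oracle: concordant pairs plus half-ties over all
    easy x difficult pairs."""
    pos = [s for s, l in zip(scores, labels) if l == "difficult"]
    neg = [s for s, l in zip(scores, labels) if l == "easy"]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_cutoff_zero_everyone_positive(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        c = confusion_at_cutoff(scores, labels, 0)
        assert c.fn == 0 and c.tn == 0
        assert c.tp == labels.count("difficult")
        assert c.fp == labels.count("easy")

    def test_cutoff_above_max_no_positives(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        c = confusion_at_cutoff(scores, labels, 20)
        assert c.tp == 0 and c.fp == 0

    def test_grouped_expansion_at_cutoff_7(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        c = confusion_at_cutoff(scores, labels, 7)
        assert (c.tp, c.fp, c.tn, c.fn) == (134, 28, 126, 31)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            confusion_at_cutoff([1, 2], ["easy"], 1)

    def test_counts_partition_cohort(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        for cut in range(0, 21):
            assert confusion_at_cutoff(scores, labels, cut).n == len(scores)


class TestMetrics:
    def test_published_row_cutoff_7(self):
        m = metrics_from_counts(ConfusionCounts(tp=134, fp=28, tn=126, fn=31))
        assert m.sensitivity == pytest.approx(134 / 165)
        assert m.specificity == pytest.approx(126 / 154)
        assert (trunc2(m.sensitivity), trunc2(m.specificity), trunc2(m.ppv)) == (
            0.81, 0.81, 0.82)
        # derivable NPV is 126/157, rendered 0.80
        assert trunc2(m.npv) == 0.80
        assert m.youden == pytest.approx(m.sensitivity + m.specificity - 1)

    def test_published_row_cutoff_2(self):
        m = metrics_from_counts(ConfusionCounts(tp=163, fp=122, tn=32, fn=2))
        assert (trunc2(m.sensitivity), trunc2(m.specificity)) == (0.98, 0.20)

    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(tp=10, fp=0, tn=12, fn=0))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.youden) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_is_none_not_zero(self):
        m = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m.ppv is None
        assert m.sensitivity == 0.0


class TestRoc:
    def test_trapezoid_equals_pair_counting_on_reference(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 19), st.booleans()),
                    min_size=4, max_size=200))
    def test_trapezoid_equals_pair_counting_random(self, data):
        scores = [s for s, _ in data]
        labels = ["difficult" if d else "easy" for _, d in data]
        if "easy" not in labels or "difficult" not in labels:
            return
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_label_inversion(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        flipped = ["easy" if l == "difficult" else "difficult" for l in labels]
        assert roc_curve(scores, flipped).auc == pytest.approx(
            1.0 - roc_curve(scores, labels).auc, abs=1e-12)

    def test_monotone_transform_invariance(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        transformed = [3 * s + 1 for s in scores]
        assert roc_curve(transformed, labels).auc == pytest.approx(
            roc_curve(scores, labels).auc, abs=1e-12)

    def test_uninformative_score(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 20, size=10_000).tolist()
        labels = ["difficult" if b else "easy" for b in rng.random(10_000) < 0.5]
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_perfect_separation(self):
        scores = [0] * 10 + [10] * 10
        labels = ["easy"] * 10 + ["difficult"] * 10
        assert roc_curve(scores, labels).auc == 1.0

    def test_anchors_and_monotone_points(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        roc = roc_curve(scores, labels)
        assert roc.points[0] == (1.0, 1.0)
        assert roc.points[-1] == (0.0, 0.0)
        fprs = [p[0] for p in roc.points]
        tprs = [p[1] for p in roc.points]
        assert fprs == sorted(fprs, reverse=True)
        assert tprs == sorted(tprs, reverse=True)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_curve([1, 2, 3], ["easy"] * 3)

    def test_ci_contains_auc(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        for method in ("hanley-mcneil", "delong"):
            roc = roc_curve(scores, labels, ci_method=method)
            assert roc.auc_ci[0] <= roc.auc <= roc.auc_ci[1]


class TestGroupedAuc:
    def test_reference_strata_exact_fraction(self):
        g = GroupedCounts(("low", "intermediate", "high"),
                          easy=(32, 94, 28), difficult=(2, 29, 134))
        assert auc_grouped(g) == pytest.approx(21083 / 25410, abs=1e-15)

    def test_identical_distributions(self):
        g = GroupedCounts(("a", "b"), easy=(10, 20), difficult=(1, 2))
        assert auc_grouped(g) == pytest.approx(0.5)

    def test_complete_separation(self):
        g = GroupedCounts(("a", "b"), easy=(30, 0), difficult=(0, 40))
        assert auc_grouped(g) == 1.0

    def test_absent_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            auc_grouped(GroupedCounts(("a", "b"), easy=(3, 4), difficult=(0, 0)))


class TestAucCI:
    def test_hanley_mcneil_published_setting(self):
        lo, hi = auc_confidence_interval(0.88, n_pos=165, n_neg=154, level=0.95)
        assert lo == pytest.approx(0.842, abs=0.001)
        assert hi == pytest.approx(0.918, abs=0.001)

    def test_interval_shrinks_with_n(self):
        lo, hi = auc_confidence_interval(0.5, 10**6, 10**6)
        assert hi - lo < 0.01

    def test_interval_contains_auc(self):
        for a in (0.55, 0.7, 0.9, 0.99):
            lo, hi = auc_confidence_interval(a, 50, 60)
            assert lo <= a <= hi

    def test_invalid_level(self):
        with pytest.raises(ValidationError):
            auc_confidence_interval(0.8, 10, 10, level=1.5)


class TestCutoffTable:
    def test_nested_monotonicity(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        rows = cutoff_table(scores, labels, list(range(1, 14)))
        sens = [r.metrics.sensitivity for r in rows]
        spec = [r.metrics.specificity for r in rows]
        tp = [r.counts.tp for r in rows]
        fp = [r.counts.fp for r in rows]
        assert sens == sorted(sens, reverse=True)
        assert spec == sorted(spec)
        assert tp == sorted(tp, reverse=True)
        assert fp == sorted(fp, reverse=True)

    def test_empty_cutoff_list(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        assert cutoff_table(scores, labels, []) == []

    def test_published_rows_at_2_and_7(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        rows = {r.cutoff: r for r in cutoff_table(scores, labels, [2, 7])}
        assert (rows[2].counts.tp, rows[2].counts.fp) == (163, 122)
        assert (rows[7].counts.tp, rows[7].counts.fp) == (134, 28)


class TestYouden:
    def test_max_youden_selected(self, reference_scores_labels):
        scores, labels = reference_scores_labels
        rows = cutoff_table(scores, labels, [1, 2, 3])
        best = youden_optimal_cutoff(rows)
        ys = {r.cutoff: r.metrics.youden for r in rows}
        assert ys[best] == max(ys.values())

    def test_tie_goes_to_smallest_cutoff(self):
        scores = [0, 0, 5, 5]
        labels = ["easy", "easy", "difficult", "difficult"]
        rows = cutoff_table(scores, labels, [1, 2, 3])
        # all three cutoffs separate perfectly -> identical youden, pick 1
        assert youden_optimal_cutoff(rows) == 1

    def test_synthetic_cohort_smoke(self):
        from lapchole.synthetic import CohortSpec, generate_frame
        df = generate_frame(CohortSpec(n=2000, seed=11))
        g = df[df["difficulty"].notna()]
        rows = cutoff_table(g["score_total"].astype(int).tolist(),
                            g["difficulty"].tolist(), list(range(1, 14)))
        best = youden_optimal_cutoff(rows)
        assert 1 <= best <= 13
        assert dict((r.cutoff, r.metrics.youden) for r in rows)[best] > 0.4
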