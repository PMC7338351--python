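"""Precision-recall metrics against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiboost.metrics import (
    MetricError,
    association_tests,
    average_precision,
    average_precision_score,
    confusion_counts,
    mean_ap,
    pr_curve,
)


def brute_force_ap(scores, labels) -> float:
    """Independent cut-off-loop oracle: recompute TP/FP/FN from scratch at
    every unique score taken as a descending threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        predicted = scores >= t
        tp = int((predicted & (labels == 1)).sum())
        fp = int((predicted & (labels == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestConfusionCounts:
    def test_two_by_two_definition(self):
        c = confusion_counts([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)
        assert c.n == 4

    def test_all_correct(self):
        c = confusion_counts([1, 0, 1], [1, 0, 1])
        assert c.fp == c.fn == 0
        assert c.precision == c.recall == 1.0

    def test_no_predicted_positives_precision_convention(self):
        c = confusion_counts([1, 0], [0, 0])
        assert c.precision == 1.0

    def test_non_binary_rejected(self):
        with pytest.raises(MetricError):
            confusion_counts([1, 2], [1, 0])


class TestPRCurve:
    def test_hand_computed_four_cutoffs(self):
        curve = pr_curve([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        np.testing.assert_allclose(curve.recall, [0.0, 0.5, 0.5, 1.0, 1.0])
        np.testing.assert_allclose(curve.precision, [1.0, 1.0, 0.5, 2 / 3, 0.5])

    def test_perfect_separation_reaches_one_one(self):
        curve = pr_curve([3.0, 2.0, 1.0, 0.5], [1, 1, 0, 0])
        points = set(zip(curve.recall, curve.precision))
        assert (1.0, 1.0) in points

    def test_all_scores_tied_single_cutoff(self):
        curve = pr_curve([0.5] * 6, [1, 1, 0, 0, 1, 0])
        assert curve.thresholds.size == 1
        assert curve.recall[-1] == 1.0
        assert curve.precision[-1] == 0.5  # prevalence

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            pr_curve([0.1, 0.2], [1, 1])


class TestAveragePrecision:
    def test_worked_example(self):
        ap = average_precision_score([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert ap == pytest.approx(5 / 6, abs=1e-12)

    def test_perfect_ranking_is_one(self):
        for prevalence in (0.2, 0.5, 0.8):
            n = 50
            pos = int(n * prevalence)
            labels = np.r_[np.ones(pos), np.zeros(n - pos)]
            scores = -np.arange(n, dtype=float)
            assert average_precision_score(scores, labels) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(4, 60)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            # mix continuous and heavily tied scores
            scores = np.round(rng.normal(size=n), rng.integers(0, 3))
            assert average_precision_score(scores, labels) == pytest.approx(
                brute_force_ap(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import average_precision_score as sk_ap

        rng = np.random.default_rng(7)
        for _ in range(50)        :
            labels = rng.integers(0, 2, 80)
            if labels.sum() in (0, 80):
                continue
            scores = rng.normal(size=80)
            assert average_precision_score(scores, labels) == pytest.approx(
                sk_ap(labels, scores), abs=1e-10
            )

    def test_random_scores_mean_near_prevalence(self):
        rng = np.random.default_rng(3)
        p, n, reps = 0.3, 2000, 200
        labels = (rng.random(n) < p).astype(int)
        prevalence = labels.mean()
        aps = [
            average_precision_score(rng.random(n), labels) for _ in range(reps)
        ]
        se = np.std(aps, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(aps) - prevalence) < 3 * se + 1e-3

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(-50, 50), st.integers(0, 1)),
            min_size=4,
            max_size=40,
        )
    )
    def test_monotone_transform_invariance(self, pairs):
        # integer scores keep the transform strictly monotone in floats
        # (ties must stay ties and non-ties stay distinct)
        scores = np.array([p[0] for p in pairs], dtype=float)
        labels = np.array([p[1] for p in pairs])
        if labels.sum() in (0, labels.size):
            return
        ap1 = average_precision_score(scores, labels)
        ap2 = average_precision_score(np.exp(scores / 2) + 7, labels)
        assert ap1 == pytest.approx(ap2, abs=1e-12)

    def test_reversed_scores_not_better(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 100)
        scores = labels + rng.normal(0, 0.5, 100)  # informative ranking
        ap = average_precision_score(scores, labels)
        assert ap > labels.mean()
        assert average_precision_score(-scores, labels) <= ap


class TestMeanAP:
    def test_single_value(self):
        m, s = mean_ap([0.5])
        assert (m, s) == (0.5, 0.0)

    def test_two_point_formula(self):
        m, s = mean_ap([0.6, 0.8])
        assert m == pytest.approx(0.7)
        assert s == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_permutation_symmetry(self):
        values = [0.3, 0.9, 0.5, 0.7]
        assert mean_ap(values) == mean_ap(values[::-1])


class TestAssociationTests:
    def test_reference_contingency_magnitude(self):
        """The oral-contraceptive 2x2 table from the published cohort gives a
        p-value of order 1e-6 under Yates-corrected chi-squared."""
        from scipy import stats

        table = [[300, 145], [124, 126]]
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
        assert p == pytest.approx(5.6e-6, rel=0.01)

    def test_emulated_cohort_recovers_the_signal(self):
        from epiboost.synthetic import emulate_reference_margins

        cohort = emulate_reference_margins(seed=2)
        table = association_tests(cohort)
        row = table[table.feature == "oral_contraceptive_use"].iloc[0]
        assert row.p_value < 1e-3
        assert "chi-squared" in row.test

    def test_continuous_p_uniform_under_null(self):
        """Welch-t p-values should be uniform when both classes share the
        feature distribution (KS sanity, 500 replicates)."""
        from scipy import stats

        from epiboost.cohort import Cohort, DemographicFeature, GenotypeMatrix

        rng = np.random.default_rng(17)
        labels = np.r_[np.ones(60, int), np.zeros(60, int)]
        gm = GenotypeMatrix(
            subjects=[f"S{i}" for i in range(120)],
            snps=[],
            codes=np.empty((120, 0), dtype=np.int8),
        )
        pvals = []
        for _ in range(500):
            feat = DemographicFeature(
                "x", "continuous", "other", rng.normal(size=120)
            )
            table = association_tests(
                Cohort(genotypes=gm, demographics=[feat], labels=labels)
            )
            pvals.append(table.p_value.iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_categorical_yates_is_conservative_under_null(self):
        """Continuity-corrected 2x2 chi-squared false-positive rate must not
        exceed the nominal level under the null."""
        from epiboost.cohort import Cohort, DemographicFeature, GenotypeMatrix

        rng = np.random.default_rng(19)
        labels = np.r_[np.ones(80, int), np.zeros(80, int)]
        gm = GenotypeMatrix(
            subjects=[f"S{i}" for i in range(160)],
            snps=[],
            codes=np.empty((160, 0), dtype=np.int8),
        )
        rejections = 0
        reps = 400
        for _ in range(reps):
            feat = DemographicFeature(
                "x", "categorical", "other", rng.integers(0, 2, 160).astype(float)
            )
            table = association_tests(
                Cohort(genotypes=gm, demographics=[feat], labels=labels)
            )
            rejections += table.p_value.iloc[0] < 0.05
        assert rejections / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_single_category_skipped_with_note(self):
        from epiboost.cohort import Cohort, DemographicFeature, GenotypeMatrix

        gm = GenotypeMatrix(
            subjects=["a", "b", "c", "d"],
            snps=[],
            codes=np.empty((4, 0), dtype=np.int8),
        )
        feat = DemographicFeature("const", "categorical", "other", [1, 1, 1, 1])
        table = association_tests(
            Cohort(genotypes=gm, demographics=[feat], labels=[1, 1, 0, 0])
        )
        assert "skipped" in table.note.iloc[0]
        assert np.isnan(table.p_value.iloc[0])


def test_plot_pr_curves_writes_file(tmp_path):
    from epiboost.metrics import plot_pr_curves, pr_curve

    curves = {
        "model": pr_curve([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]),
        "baseline": pr_curve([0.1, 0.8, 0.3, 0.6], [1, 0, 1, 0]),
    }
    out = tmp_path / "pr.png"
    plot_pr_curves(curves, path=out)
    assert out.exists() and out.stat().st_size > 0
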