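"""ROC construction, AUC identities, Youden cut-off selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glimcrp import (
    auc,
    build_roc,
    generate_cohort,
    sens_spec_at,
    windowed_subgroup_analysis,
    youden_optimal,
)
from glimcrp.pipeline import prepare_cohort
from glimcrp.roc_stats import reports_to_table

from conftest import make_spec, null_outcome_model


def pair_count_auc(scores, labels):
    """Brute-force oracle: P(random positive outranks random negative), ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


def brute_force_youden(scores, labels):
    """Exhaustive J maximisation over observed values, ties broken low."""
    best = None
    for cut in sorted(set(scores)):
        called = np.asarray(scores) >= cut
        labels_ = np.asarray(labels, bool)
        sens = (called & labels_).sum() / labels_.sum()
        spec = (~called & ~labels_).sum() / (~labels_).sum()
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, cut)
    return best


SCORES4 = [0.1, 0.4, 0.35, 0.8]
LABELS4 = [False, False, True, True]


class TestBuildRoc:
    def test_hand_enumerated_curve(self):
        curve = build_roc(SCORES4, LABELS4)
        np.testing.assert_allclose(curve.thresholds, [np.inf, 0.8, 0.4, 0.35, 0.1])
        np.testing.assert_allclose(curve.sensitivity, [0, 0.5, 0.5, 1.0, 1.0])
        np.testing.assert_allclose(curve.specificity, [1, 1.0, 0.5, 0.5, 0.0])

    def test_curve_spans_unit_square(self):
        curve = build_roc(SCORES4, LABELS4)
        assert (curve.sensitivity[0], 1 - curve.specificity[0]) == (0, 0)
        assert (curve.sensitivity[-1], 1 - curve.specificity[-1]) == (1, 1)

    def test_perfect_separation_hits_top_left(self):
        curve = build_roc([1, 2, 10, 11], [False, False, True, True])
        assert any(
            s == 1.0 and p == 1.0
            for s, p in zip(curve.sensitivity, curve.specificity)
        )

    def test_constant_scores_single_threshold(self):
        curve = build_roc([5.0] * 6, [True, False] * 3)
        assert curve.thresholds.size == 2  # sentinel + the single value
        assert curve.sensitivity[-1] == 1.0 and curve.specificity[-1] == 0.0

    def test_degenerate_labels_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_roc([1, 2, 3], [True, True, True])


class TestAuc:
    def test_three_quarters_example(self):
        assert auc(build_roc(SCORES4, LABELS4)) == pytest.approx(0.75)

    def test_perfect_separation_is_one(self):
        assert auc(build_roc([1, 2, 10, 11], [False, False, True, True])) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(42)
        scores = rng.random(10000)
        labels = rng.random(10000) < 0.4
        assert auc(build_roc(scores, labels)) == pytest.approx(0.5, abs=0.02)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_trapezoid_equals_pair_count(self, data):
        n = data.draw(st.integers(4, 50))
        scores = data.draw(
            st.lists(st.floats(0, 10), min_size=n, max_size=n).map(
                lambda xs: [round(x, 1) for x in xs]  # force ties
            )
        )
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        got = auc(build_roc(scores, labels))
        assert got == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_label_flip_maps_auc_to_complement(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=300).round(1)
        labels = rng.random(300) < 0.5
        a = auc(build_roc(scores, labels))
        assert auc(build_roc(scores, ~labels)) == pytest.approx(1 - a, abs=1e-12)
        assert auc(build_roc(-scores, ~labels)) == pytest.approx(a, abs=1e-12)


class TestYouden:
    def test_tie_broken_toward_smaller_cutoff(self):
        report = youden_optimal(build_roc(SCORES4, LABELS4))
        assert report.optimal_cutoff == pytest.approx(0.35)
        assert report.youden_j == pytest.approx(0.5)

    def test_perfect_separation(self):
        report = youden_optimal(build_roc([1, 2, 10, 11], [False, False, True, True]))
        assert report.optimal_cutoff == 10
        assert report.youden_j == pytest.approx(1.0)

    def test_constant_scores_zero_j(self):
        report = youden_optimal(build_roc([5.0] * 6, [True, False] * 3))
        assert report.youden_j == pytest.approx(0.0)
        assert np.isfinite(report.optimal_cutoff)

    def test_j_consistency_invariant(self):
        report = youden_optimal(build_roc(SCORES4, LABELS4))
        assert report.youden_j == pytest.approx(
            report.sens_at_cutoff + report.spec_at_cutoff - 1
        )

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force(self, data):
        n = data.draw(st.integers(4, 40))
        scores = data.draw(
            st.lists(st.floats(0, 5), min_size=n, max_size=n).map(
                lambda xs: [round(x, 1) for x in xs]
            )
        )
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        j_expect, cut_expect = brute_force_youden(scores, labels)
        report = youden_optimal(build_roc(scores, labels))
        assert report.youden_j == pytest.approx(j_expect, abs=1e-12)
        assert report.optimal_cutoff == pytest.approx(cut_expect)


class TestSensSpecAt:
    def test_extreme_cutoffs(self):
        scores, labels = [1, 2, 3, 4], [False, False, True, True]
        assert sens_spec_at(scores, labels, 0.0) == (1.0, 0.0)
        assert sens_spec_at(scores, labels, 99.0) == (0.0, 1.0)

    def test_direct_count_at_interior_cutoff(self):
        scores, labels = [1, 2, 3, 4], [False, False, True, True]
        # ">= 2" calls 2,3,4 positive: one false positive
        assert sens_spec_at(scores, labels, 2.0, strict=False) == (1.0, 0.5)
        # "> 2" calls 3,4 positive: clean split
        assert sens_spec_at(scores, labels, 2.0, strict=True) == (1.0, 1.0)


class TestSklearnCrossCheck:
    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=500).round(1)
        labels = rng.random(500) < 0.3
        assert auc(build_roc(scores, labels)) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


@pytest.fixture(scope="module")
def reports(analysed_cohort):
    return windowed_subgroup_analysis(analysed_cohort)


class TestWindowedSubgroups:
    def test_cardinality_is_54(self, reports):
        assert len(reports) == 2 * 3 * 9

    def test_one_cutoff_per_population_subgroup_row(self, reports):
        table = reports_to_table(reports)
        assert len(table) == 18
        defined = table.loc[~table["undefined"]]
        assert defined["optimal_cutoff"].notna().all()

    def test_null_cohort_aucs_near_half(self):
        spec = make_spec(
            n_patients=10000, seed=19, outcome_model=null_outcome_model(),
            ineligible_fraction=0.0,
        )
        cohort = prepare_cohort(generate_cohort(spec))
        reports = windowed_subgroup_analysis(cohort)
        overall = [
            r for r in reports if r.subgroup == "all" and r.population == "all_case"
        ]
        for r in overall:
            assert r.auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_subgroup_marked_undefined(self, analysed_cohort):
        sub = analysed_cohort.copy()
        sub.loc[sub["diagnosis_category"] == "sepsis", "composite"] = True
        reports = windowed_subgroup_analysis(sub)
        sepsis = [r for r in reports if r.subgroup == "sepsis" and r.population == "all_case"]
        assert all(r.undefined for r in sepsis)
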