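"""Evaluation machinery: adjudication, confusion, exact CIs, kappa, strata."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pleurascan import (
    ConfusionMatrix,
    RatingRecord,
    adjudicate,
    characteristics,
    cohen_kappa,
    confusion,
    exact_binomial_ci,
    kappa_band,
    round_percent,
    stratified_report,
)
from pleurascan.errors import (
    SingleRaterError,
    UndefinedKappaError,
    UnknownStratumError,
    UnmatchedExamsError,
)

# The pilot evaluation's published 2x2 counts against the expert panel.
STUDY_CM = ConfusionMatrix(tp=33, fp=12, tn=79, fn=9)


def bisect_clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Independent oracle: invert exact binomial tail sums by bisection."""
    alpha = 1.0 - level
    coeff = [math.comb(n, i) for i in range(n + 1)]

    def tail_ge(p):  # P(X >= k | p)
        return sum(coeff[i] * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))

    def tail_le(p):  # P(X <= k | p)
        return sum(coeff[i] * p**i * (1 - p) ** (n - i) for i in range(k + 1))

    def bisect(f, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else bisect(tail_ge, alpha / 2, increasing=True)
    upper = 1.0 if k == n else bisect(tail_le, alpha / 2, increasing=False)
    return lower, upper


def _ratings(exam_id, labels, qualities):
    return [
        RatingRecord(exam_id, f"r{i+1}", lab, q)
        for i, (lab, q) in enumerate(zip(labels, qualities))
    ]


class TestAdjudication:
    def test_unanimous_high_quality_included(self):
        res = adjudicate(_ratings("e1", ["negative"] * 3, [4, 4, 5]))
        (exam,) = res.exams
        assert exam.included and exam.consensus_label == "negative"

    def test_unanimous_low_quality_excluded(self):
        res = adjudicate(_ratings("e1", ["positive"] * 3, [2, 2, 2]))
        (exam,) = res.exams
        assert not exam.included
        assert exam.excluded_reason == "quality_below_3"

    def test_disagreement_flagged_non_unanimous(self):
        res = adjudicate(_ratings("e1", ["positive", "positive", "negative"], [4, 4, 4]))
        (exam,) = res.exams
        assert not exam.included
        assert exam.excluded_reason == "non_unanimous"

    def test_quality_rule_off_keeps_low_quality(self):
        res = adjudicate(_ratings("e1", ["positive"] * 3, [2, 2, 2]), quality_rule=False)
        assert res.exams[0].included

    def test_single_rater_rejected(self):
        with pytest.raises(SingleRaterError):
            adjudicate(_ratings("e1", ["positive"], [4]))

    def test_excluded_exams_carry_exactly_one_reason(self):
        recs = _ratings("e1", ["positive", "negative", "negative"], [1, 1, 2])
        res = adjudicate(recs)
        (exam,) = res.exams
        assert exam.excluded_reason == "non_unanimous"  # plenary review first


class TestConfusion:
    def test_perfect_agreement(self):
        ref = {f"p{i}": "positive" for i in range(4)}
        ref.update({f"n{i}": "negative" for i in range(6)})
        cm = confusion(ref, ref)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (4, 6, 0, 0)

    def test_prediction_indeterminate_policies(self):
        ref = {"a": "positive", "b": "negative", "c": "negative"}
        pred = {"a": "indeterminate", "b": "negative", "c": "negative"}
        excl = confusion(pred, ref, "exclude")
        assert excl.total == 2
        err = confusion(pred, ref, "as_error")
        assert err.total == 3 and err.fn == 1

    def test_reference_indeterminate_always_dropped(self):
        ref = {"a": "positive", "b": "indeterminate"}
        pred = {"a": "positive", "b": "negative"}
        cm = confusion(pred, ref)
        assert cm.total == 1

    def test_unmatched_exam_ids_raise(self):
        with pytest.raises(UnmatchedExamsError):
            confusion({"a": "positive"}, {"b": "positive"})

    def test_reconstructed_study_cohort_counts(self):
        """A 133-exam set with the published error pattern reproduces the 2x2."""
        ref, pred = {}, {}
        spec_counts = [("tp", "positive", "positive", 33),
                       ("fn", "positive", "negative", 9),
                       ("tn", "negative", "negative", 79),
                       ("fp", "negative", "positive", 12)]
        i = 0
        for _, truth, guess, count in spec_counts:
            for _ in range(count):
                ref[f"e{i}"] = truth
                pred[f"e{i}"] = guess
                i += 1
        cm = confusion(pred, ref)
        assert cm == STUDY_CM
        assert cm.total == 133


class TestExactBinomialCI:
    def test_boundaries_exact(self):
        assert exact_binomial_ci(0, 10)[0] == 0.0
        assert exact_binomial_ci(10, 10)[1] == 1.0

    @pytest.mark.parametrize("k,n", [(33, 42), (79, 91), (1, 7), (25, 50)])
    def test_matches_tail_bisection_oracle(self, k, n):
        got = exact_binomial_ci(k, n)
        want = bisect_clopper_pearson(k, n)
        assert got[0] == pytest.approx(want[0], abs=1e-6)
        assert got[1] == pytest.approx(want[1], abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_ci(0, 0)

    def test_coverage_of_true_proportion(self):
        """Exact CIs cover p=0.8 at at least the nominal rate (n=42)."""
        rng = np.random.default_rng(2024)
        draws = rng.binomial(42, 0.8, size=1000)
        covered = sum(
            lo <= 0.8 <= hi
            for lo, hi in (exact_binomial_ci(int(k), 42) for k in draws)
        )
        assert covered / 1000 >= 0.93


class TestCharacteristics:
    def test_study_counts_reproduce_printed_percentages(self):
        tc = characteristics(STUDY_CM)
        # exact upper sensitivity bound is 89.70%; it rounds to 90
        assert tc.sensitivity.as_percent() == (79, 63, 90)
        assert tc.specificity.as_percent() == (87, 78, 93)
        assert tc.ppv.as_percent() == (73, 58, 85)
        assert tc.npv.as_percent() == (90, 81, 95)

    def test_zero_denominators_are_undefined_not_zero(self):
        tc = characteristics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
        assert tc.sensitivity is None
        assert tc.ppv is None
        assert tc.specificity.point == 1.0
        assert tc.npv.point == 1.0

    def test_ci_bounds_bracket_point(self):
        tc = characteristics(STUDY_CM)
        for p in (tc.sensitivity, tc.specificity, tc.ppv, tc.npv):
            assert p.lower <= p.point <= p.upper

    def test_rounding_half_away_from_zero(self):
        assert round_percent(0.785) == 79
        assert round_percent(0.125) == 13


class TestCohenKappa:
    def test_identical_ratings_kappa_one(self):
        labels = ["positive", "negative", "positive", "negative", "indeterminate"]
        assert cohen_kappa(labels, labels).kappa == 1.0

    def test_balanced_2x2_table_hand_computed(self):
        """a=45, b=5, c=5, d=45: kappa = (0.9 - 0.5)/(1 - 0.5) = 0.8 exactly."""
        a = ["positive"] * 50 + ["negative"] * 50
        b = (["positive"] * 45 + ["negative"] * 5
             + ["positive"] * 5 + ["negative"] * 45)
        res = cohen_kappa(a, b)
        assert res.kappa == 0.8
        assert res.band == "excellent"

    def test_matches_sklearn_on_random_tables(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.choice(["positive", "negative", "indeterminate"], size=60)
            b = rng.choice(["positive", "negative", "indeterminate"], size=60)
            assert cohen_kappa(list(a), list(b)).kappa == pytest.approx(
                cohen_kappa_score(a, b)
            )

    def test_undefined_when_expected_agreement_is_one(self):
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(["positive"] * 5, ["positive"] * 5)

    def test_interpretation_bands(self):
        assert kappa_band(0.84) == "excellent"
        assert kappa_band(0.6) == "fair to good"
        assert kappa_band(0.2) == "poor"

    @given(
        labels=st.lists(
            st.tuples(
                st.sampled_from(["positive", "negative"]),
                st.sampled_from(["positive", "negative"]),
            ),
            min_size=4,
            max_size=40,
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_symmetry_and_upper_bound(self, labels):
        a = [x for x, _ in labels]
        b = [y for _, y in labels]
        try:
            ab = cohen_kappa(a, b)
        except UndefinedKappaError:
            return
        ba = cohen_kappa(b, a)
        assert ab.kappa == pytest.approx(ba.kappa)
        assert ab.kappa <= 1.0 + 1e-12


class TestStratifiedReport:
    def _make_cohort_tables(self):
        ref, pred, meta = {}, {}, {}
        rng = np.random.default_rng(8)
        for i in range(60):
            e = f"e{i}"
            truth = "positive" if i % 3 == 0 else "negative"
            ref[e] = truth
            pred[e] = truth if rng.random() < 0.85 else (
                "negative" if truth == "positive" else "positive"
            )
            meta[e] = {
                "quality_score": int(rng.choice([3, 4, 5])),
                "mode": "B" if i % 4 else "M",
                "transducer": "linear" if i % 2 else "phased",
            }
        return pred, ref, meta

    def test_quality_strata_plus_overall(self):
        pred, ref, meta = self._make_cohort_tables()
        report = stratified_report(pred, ref, meta, strata=["quality"])
        assert set(report["strata"]["quality"]) == {3, 4, 5}
        assert report["overall"].confusion.total == 60

    def test_single_stratum_equals_overall(self):
        pred = {"a": "positive", "b": "negative", "c": "negative"}
        ref = {"a": "positive", "b": "negative", "c": "positive"}
        meta = {e: {"mode": "B"} for e in ref}
        report = stratified_report(pred, ref, meta, strata=["mode"])
        assert report["strata"]["mode"]["B"].confusion == report["overall"].confusion

    def test_strata_sum_to_overall(self):
        """Confusion matrices over any partition add cell-wise to the total."""
        pred, ref, meta = self._make_cohort_tables()
        report = stratified_report(pred, ref, meta)
        overall = report["overall"].confusion
        for stratum, per_level in report["strata"].items():
            total = None
            for sr in per_level.values():
                total = sr.confusion if total is None else total + sr.confusion
            assert total == overall, stratum

    def test_unknown_stratum_rejected(self):
        with pytest.raises(UnknownStratumError):
            stratified_report({}, {}, {}, strata=["operator"])
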