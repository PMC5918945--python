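"""Unit, oracle, and property tests for the diagnostic-evaluation statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bht.cohort import reference_summary
from bht.validation import (
    ContingencyTable2x2,
    build_2x2,
    confusion_metrics,
    odds_ratio_woolf,
    optimal_cutoff,
    pearson_r,
    percent,
    roc_curve,
    round_half_up,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def mann_whitney_auc(scores, labels):
    """Exhaustive pairwise P(pos < neg) + 0.5 P(pos == neg), low score = diseased."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p < n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Best (J, threshold) by trying every integer threshold, low ties first."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    best = None
    for t in range(min(scores + [0]), max(scores) + 2):
        sens = sum(s < t for s in pos) / len(pos)
        spec = sum(s >= t for s in neg) / len(neg)
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, t)
    return best


score_label_cohorts = st.lists(
    st.tuples(st.integers(0, 16), st.booleans()), min_size=2, max_size=40
).filter(lambda rows: any(y for _, y in rows) and any(not y for _, y in rows))


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(2.25, 2.3), (2.24, 2.2), (-2.25, -2.3), (3.55, 3.6), (46.45, 46.5)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_up(x) == expected

    def test_percent(self):
        assert percent(635 / 647) == 98.1


class TestConfusionMetrics:
    def test_printed_triage_sensitivity(self):
        cm = confusion_metrics(tp=635, fp=89, tn=77, fn=12)
        assert cm.as_percent()["sensitivity"] == 98.1

    def test_perfect_classifier(self):
        cm = confusion_metrics(tp=5, fp=0, tn=7, fn=0).as_percent()
        assert cm == {"sensitivity": 100.0, "specificity": 100.0, "ppv": 100.0, "npv": 100.0}

    def test_hand_computed_ratios(self):
        cm = confusion_metrics(tp=3, fp=1, tn=2, fn=2).as_percent()
        assert cm == {"sensitivity": 60.0, "specificity": 66.7, "ppv": 75.0, "npv": 50.0}

    def test_zero_denominator_is_undefined_not_zero(self):
        cm = confusion_metrics(tp=0, fp=0, tn=5, fn=3)
        assert cm.ppv is None
        assert cm.sensitivity == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(tp=-1, fp=0, tn=1, fn=0)

    @given(st.integers(1, 200), st.integers(0, 200), st.integers(1, 200), st.integers(0, 200))
    def test_bayes_consistency(self, tp, fp, tn, fn):
        # ppv must equal sens*prev / (sens*prev + (1-spec)(1-prev))
        cm = confusion_metrics(tp=tp, fp=fp, tn=tn, fn=fn)
        prev = (tp + fn) / (tp + fp + tn + fn)
        num = cm.sensitivity * prev
        den = num + (1 - cm.specificity) * (1 - prev)
        if den > 0:
            assert cm.ppv == pytest.approx(num / den)


class TestOddsRatioWoolf:
    def test_published_memory_complaint_table(self):
        result = odds_ratio_woolf(ContingencyTable2x2(614, 33, 72, 94))
        assert result.rounded() == (24.3, 15.2, 38.7)
        assert not result.corrected

    def test_symmetric_table_is_unity(self):
        assert odds_ratio_woolf(ContingencyTable2x2(10, 10, 10, 10)).estimate == 1.0

    def test_zero_cell_haldane_correction(self):
        # hand-recomputed on the corrected table: (5.5 * 7.5) / (0.5 * 3.5) = 23.571...
        result = odds_ratio_woolf(ContingencyTable2x2(5, 0, 3, 7))
        assert result.corrected
        assert result.estimate == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))
        assert result.rounded()[0] == 23.6

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError):
            odds_ratio_woolf(ContingencyTable2x2(0, 0, 3, 7))

    def test_ci_matches_direct_formula(self):
        a, b, c, d = 153, 494, 14, 152
        result = odds_ratio_woolf(ContingencyTable2x2(a, b, c, d))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert result.ci_low == pytest.approx(result.estimate * math.exp(-1.959964 * se), rel=1e-5)
        assert result.ci_high == pytest.approx(result.estimate * math.exp(1.959964 * se), rel=1e-5)

    @given(st.tuples(*[st.integers(0, 50)] * 4).filter(
        lambda t: t[0] + t[1] > 0 and t[2] + t[3] > 0 and t[0] + t[2] > 0 and t[1] + t[3] > 0))
    def test_exposure_swap_inverts(self, cells):
        a, b, c, d = cells
        fwd = odds_ratio_woolf(ContingencyTable2x2(a, b, c, d))
        rev = odds_ratio_woolf(ContingencyTable2x2(b, a, d, c))
        assert fwd.estimate * rev.estimate == pytest.approx(1.0)

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(TypeError):
            ContingencyTable2x2(1.5, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([0, 0, 16, 16], [True, True, False, False])
        assert roc.auc == 1.0
        assert roc.auc_ci == (1.0, 1.0)

    def test_uninformative_scores(self):
        roc = roc_curve([7, 7, 7, 7], [True, False, True, False])
        assert roc.auc == pytest.approx(0.5)

    def test_five_subject_example_matches_pairwise_count(self):
        scores = [2, 4, 9, 11, 13]
        labels = [True, True, True, False, False]
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, labels))
        assert roc.auc == 1.0

    def test_tie_contributes_half(self):
        scores = [2, 4, 9, 9, 13]
        labels = [True, True, True, False, False]
        roc = roc_curve(scores, labels)
        assert mann_whitney_auc(scores, labels) == pytest.approx(5.5 / 6)
        assert roc.auc == pytest.approx(5.5 / 6)

    def test_endpoints_and_monotonicity(self):
        roc = roc_curve([1, 5, 5, 9, 12], [True, True, False, False, False])
        assert roc.points[0] == (0.0, 0.0)
        assert roc.points[-1] == (1.0, 1.0)
        xs, ys = zip(*roc.points)
        assert all(x1 <= x2 for x1, x2 in zip(xs, xs[1:]))
        assert all(y1 <= y2 for y1, y2 in zip(ys, ys[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [True, True, True])

    def test_positive_high_orientation(self):
        # flipping score orientation mirrors the AUC
        scores = [2, 4, 9, 11, 13]
        labels = [True, True, True, False, False]
        low = roc_curve(scores, labels, positive_low=True)
        high = roc_curve(scores, labels, positive_low=False)
        assert high.auc == pytest.approx(1.0 - low.auc)
        xs, ys = zip(*high.points)
        assert all(x1 <= x2 for x1, x2 in zip(xs, xs[1:]))

    @settings(max_examples=200)
    @given(score_label_cohorts)
    def test_trapezoid_equals_mann_whitney(self, rows):
        scores = [s for s, _ in rows]
        labels = [y for _, y in rows]
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, labels))
        assert 0.0 <= roc.auc <= 1.0


class TestOptimalCutoff:
    def test_perfect_separation_threshold(self):
        roc = roc_curve([0, 1, 12, 14], [True, True, False, False])
        best = optimal_cutoff(roc)
        assert best.youden_j == pytest.approx(1.0)
        assert 2 <= best.threshold <= 12

    def test_flat_curve_tie_breaks_low(self):
        roc = roc_curve([7, 7, 7, 7], [True, False, True, False])
        best = optimal_cutoff(roc)
        assert best.youden_j == pytest.approx(0.0)
        assert best.threshold == roc.thresholds[0]

    @settings(max_examples=100)
    @given(score_label_cohorts)
    def test_matches_exhaustive_search(self, rows):
        scores = [s for s, _ in rows]
        labels = [y for _, y in rows]
        best = optimal_cutoff(roc_curve(scores, labels))
        j_oracle, t_oracle = exhaustive_youden(scores, labels)
        assert best.youden_j == pytest.approx(j_oracle)
        assert best.threshold == t_oracle


class TestPearson:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_small_set_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        assert pearson_r(x, y) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])


class TestBuild2x2:
    def test_assistance_need_from_reference_summary(self):
        table = build_2x2(reference_summary(), "needs_assistance_money_meds",
                          ["mci", "dementia"])
        assert (table.a, table.b, table.c, table.d) == (309, 338, 9, 157)

    def test_head_trauma_from_reference_summary(self):
        table = build_2x2(reference_summary(), "head_trauma_loc", ["mci", "dementia"])
        assert (table.a, table.b, table.c, table.d) == (57, 590, 6, 160)

    def test_absent_factor_gives_zero_exposed(self, toy_cohort):
        table = build_2x2(toy_cohort, "stroke", ["mci", "dementia"])
        assert table.a == 0 and table.c == 0

    def test_record_level_cohort(self, toy_cohort):
        table = build_2x2(toy_cohort, "memory_decline_subject", ["mci", "dementia"])
        assert (table.a, table.b, table.c, table.d) == (4, 0, 0, 2)

    def test_unknown_factor_rejected(self):
        with pytest.raises(KeyError):
            build_2x2(reference_summary(), "nope", ["dementia"])

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            build_2x2(reference_summary(), "stroke", ["dementia", "zombie"])
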