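"""Confusion matrices, exact binomial CIs, majority voting, crosshair export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom

from ppgdx.evaluation import (
    ConfusionMatrix,
    combine_confusions,
    crosshair_export,
    exact_ci,
    majority_vote,
    metrics,
    participant_votes,
    round_half_up,
)


def brute_force_clopper_pearson(k: int, n: int, alpha: float = 0.05):
    """Independent oracle: invert the binomial tail sums by bisection."""

    def upper_tail(p):  # P(X >= k)
        return 1.0 - binom.cdf(k - 1, n, p)

    def lower_tail(p):  # P(X <= k)
        return binom.cdf(k, n, p)

    def bisect(f, target, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < target:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    lo = 0.0 if k == 0 else bisect(lambda p: upper_tail(p), alpha / 2, 1.0, 0.0)
    hi = 1.0 if k == n else bisect(lambda p: lower_tail(p), alpha / 2, 0.0, 1.0)
    return 100 * min(lo, hi) if k else 0.0, 100 * max(lo, hi) if k != n else 100.0


class TestExactCI:
    @pytest.mark.parametrize("k,n", [(1, 5), (15, 20), (44, 51), (0, 10), (10, 10), (35, 71)])
    def test_matches_binomial_tail_inversion(self, k, n):
        got = exact_ci(k, n)
        want = brute_force_clopper_pearson(k, n)
        assert got[0] == pytest.approx(want[0], abs=1e-6)
        assert got[1] == pytest.approx(want[1], abs=1e-6)

    def test_zero_successes_lower_bound(self):
        lo, hi = exact_ci(0, 10)
        assert lo == 0.0 and hi > 0.0

    def test_all_successes_upper_bound(self):
        lo, hi = exact_ci(10, 10)
        assert hi == 100.0 and lo < 100.0

    @given(n=st.integers(min_value=1, max_value=120), k_frac=st.floats(0, 1))
    def test_interval_contains_point_estimate(self, n, k_frac):
        k = int(round(k_frac * n))
        lo, hi = exact_ci(k, n)
        assert lo <= 100.0 * k / n <= hi

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_ci(5, 4)
        with pytest.raises(ValueError):
            exact_ci(-1, 4)


class TestConfusionAndMetrics:
    def test_combine_is_elementwise_sum(self):
        a = ConfusionMatrix(1, 0, 0, 1)
        b = ConfusionMatrix(2, 1, 1, 0)
        assert combine_confusions([a, b]) == ConfusionMatrix(3, 1, 1, 1)
        assert combine_confusions([a]) == a

    def test_combine_order_invariant(self):
        ms = [ConfusionMatrix(i, 2 * i, 1, 3) for i in range(1, 5)]
        assert combine_confusions(ms) == combine_confusions(ms[::-1])

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(1, 0, 0, 1))
        assert m.accuracy == m.sensitivity == m.specificity == 100.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 3, 4))
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(3, 4, 0, 0))

    def test_from_predictions(self):
        cm = ConfusionMatrix.from_predictions(
            ["SSc", "SSc", "Control", "Control"], ["SSc", "Control", "SSc", "Control"])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 1)


class TestMajorityVote:
    def test_clear_majority(self):
        assert majority_vote(["SSc"] * 130 + ["Control"] * 110) == "SSc"
        assert majority_vote(["SSc"] * 100 + ["Control"] * 140) == "Control"

    def test_exact_tie_goes_to_positive_class(self):
        assert majority_vote(["SSc"] * 120 + ["Control"] * 120) == "SSc"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_brute_force_oracle_all_splits(self):
        # all 241 splits of 240 images: argmax with ties resolved to SSc
        for n_ssc in range(241):
            labels = ["SSc"] * n_ssc + ["Control"] * (240 - n_ssc)
            expected = "SSc" if n_ssc >= 240 - n_ssc else "Control"
            assert majority_vote(labels) == expected

    def test_participant_votes_aggregation(self):
        df = pd.DataFrame({
            "participant_id": ["A"] * 3 + ["B"] * 2,
            "true_label": ["SSc"] * 3 + ["Control"] * 2,
            "predicted_label": ["SSc", "Control", "SSc", "Control", "Control"],
        })
        out = participant_votes(df).set_index("participant_id")
        assert out.loc["A", "predicted_label"] == "SSc"
        assert out.loc["B", "predicted_label"] == "Control"
        assert out.loc["A", "n_images"] == 3


class TestCrosshairExport:
    def test_fpr_transform_with_swapped_endpoints(self):
        m = metrics(ConfusionMatrix(15, 5, 7, 44))
        df = crosshair_export({"cnn": m}).iloc[0]
        assert df["fpr"] == pytest.approx(100.0 - m.specificity)
        assert df["fpr_ci_low"] == pytest.approx(100.0 - m.specificity_ci[1])
        assert df["fpr_ci_high"] == pytest.approx(100.0 - m.specificity_ci[0])
        assert df["sensitivity"] == pytest.approx(m.sensitivity)

    def test_row_count_matches_input(self):
        m = metrics(ConfusionMatrix(3, 1, 1, 3))
        assert len(crosshair_export({"a": m, "b": m, "c": m})) == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            crosshair_export({})


def test_round_half_up():
    assert round_half_up(86.95, 1) == 87.0
    assert round_half_up(73.662, 1) == 73.7
    assert round_half_up(83.098, 1) == 83.1
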