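"""Score conventions, ROC/AUC, MCC, rank tests: examples and oracle checks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from pgxtypeb.io import ToolScoreTable
from pgxtypeb.metrics import (
    DEFAULT_CONVENTIONS,
    auc,
    auc_scores,
    cadd_phred_to_rank_fraction,
    group_summary,
    mann_whitney_u,
    mcc,
    mcc_at_threshold,
    mcc_best_threshold,
    normalize_scores,
    paired_one_sided_t_test,
    polyphen2_bin,
    roc_curve,
)


def _table(values_by_tool, groups):
    idx = pd.Index([f"rs{i}" for i in range(len(groups))], name="rsid")
    df = pd.DataFrame(values_by_tool, dtype=float).set_axis(idx)
    return ToolScoreTable(list(values_by_tool), df, pd.Series(groups, index=idx))


class TestNormalization:
    def test_sift_zero_becomes_most_damaging(self):
        table = _table({"SIFT": [0.0, 1.0, 0.25]}, ["1", "1", "random"])
        out = normalize_scores(table)
        assert out.scores["SIFT"].tolist() == [1.0, 0.0, 0.75]

    def test_cadd_minmax_over_reference(self):
        table = _table({"CADD": [0.0, 50.0, 25.0]}, ["1", "random", "random"])
        out = normalize_scores(table)
        assert out.scores["CADD"].tolist() == [0.0, 1.0, 0.5]

    def test_identity_tool_unchanged(self):
        table = _table({"PolyPhen2": [0.37]}, ["1"])
        assert normalize_scores(table).scores["PolyPhen2"].tolist() == [0.37]

    def test_missing_stays_missing(self):
        table = _table({"CADD": [0.0, 10.0, np.nan]}, ["1", "1", "1"])
        assert np.isnan(normalize_scores(table).scores["CADD"].iloc[2])

    def test_degenerate_minmax_reference_rejected(self):
        table = _table({"CADD": [5.0, 5.0]}, ["1", "random"])
        with pytest.raises(ValueError, match="CADD"):
            normalize_scores(table)

    def test_reference_restricts_minmax_rows(self):
        table = _table({"CADD": [0.0, 10.0, 100.0]}, ["1", "random", "2"])
        out = normalize_scores(table, reference=["rs0", "rs1"])
        # rs2 is outside the reference range and clips to 1
        assert out.scores["CADD"].tolist() == [0.0, 1.0, 1.0]

    @given(st.lists(st.floats(0, 50), min_size=2, max_size=20, unique=True))
    def test_minmax_is_monotone(self, raw):
        table = _table({"CADD": raw}, ["1"] * len(raw))
        out = normalize_scores(table).scores["CADD"].to_numpy()
        order = np.argsort(raw)
        assert np.all(np.diff(out[order]) >= 0)


class TestCategoricalConventions:
    @pytest.mark.parametrize(
        "score,label",
        [
            (0.0, "benign"),
            (0.1499, "benign"),
            (0.15, "possibly damaging"),
            (0.84, "possibly damaging"),
            (0.85, "probably damaging"),
            (0.996, "probably damaging"),
            (1.0, "probably damaging"),
        ],
    )
    def test_polyphen2_bins(self, score, label):
        assert polyphen2_bin(score) == label

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_polyphen2_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            polyphen2_bin(bad)

    @pytest.mark.parametrize("phred,frac", [(30.0, 0.001), (20.0, 0.01), (10.0, 0.1), (0.0, 1.0)])
    def test_cadd_phred_rank_fraction(self, phred, frac):
        assert cadd_phred_to_rank_fraction(phred) == pytest.approx(frac)

    def test_negative_phred_rejected(self):
        with pytest.raises(ValueError):
            cadd_phred_to_rank_fraction(-1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_curve([0.9, 0.8], [0.1, 0.2])
        assert (0.0, 1.0) in curve.points
        assert auc(curve) == 1.0

    def test_identical_samples_trace_diagonal(self):
        curve = roc_curve([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert all(fpr == tpr for fpr, tpr in curve.points)
        assert auc(curve) == pytest.approx(0.5)

    def test_tied_example_area(self):
        assert auc_scores([0.8, 0.3], [0.5, 0.3]) == pytest.approx(0.625)

    def test_empty_side_error_names_side(self):
        with pytest.raises(ValueError, match="negative"):
            roc_curve([0.5], [np.nan])
        with pytest.raises(ValueError, match="positive"):
            roc_curve([], [0.5])

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=10),
        st.lists(st.integers(0, 5), min_size=1, max_size=10),
    )
    def test_complementarity(self, xs, ys):
        assert auc_scores(xs, ys) + auc_scores(ys, xs) == pytest.approx(1.0, abs=1e-12)

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
    )
    def test_auc_equals_midrank_u_statistic(self, xs, ys):
        # independent route: scipy's U (midrank ties) normalized by n1*n2
        u = stats.mannwhitneyu(xs, ys, alternative="two-sided").statistic
        assert auc_scores(xs, ys) == pytest.approx(u / (len(xs) * len(ys)), abs=1e-12)

    def test_matches_sklearn_on_random_scores(self, rng):
        pos = rng.normal(0.6, 0.2, 60)
        neg = rng.normal(0.4, 0.2, 80)
        expected = roc_auc_score([1] * 60 + [0] * 80, np.concatenate([pos, neg]))
        assert auc_scores(pos, neg) == pytest.approx(expected, abs=1e-12)


class TestMcc:
    def test_perfect_prediction(self):
        assert mcc(10, 0, 0, 15) == 1.0

    def test_all_predicted_positive_is_zero_by_convention(self):
        assert mcc(10, 15, 0, 0) == 0.0

    def test_worked_example(self):
        assert mcc(5, 3, 4, 18) == pytest.approx((5 * 18 - 3 * 4) / math.sqrt(8 * 9 * 21 * 22))

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_bounded(self, counts):
        assert -1.0 <= mcc(*counts) <= 1.0

    def test_best_threshold_matches_brute_force(self, rng):
        for _ in range(50):
            pos = rng.integers(0, 10, rng.integers(1, 8)) / 10
            neg = rng.integers(0, 10, rng.integers(1, 8)) / 10
            t, m = mcc_best_threshold(pos, neg)
            brute = max(
                mcc_at_threshold(pos, neg, float(c))
                for c in np.unique(np.concatenate([pos, neg]))
            )
            assert m == pytest.approx(brute)
            assert mcc_at_threshold(pos, neg, t) == pytest.approx(m)

    def test_perfectly_separated_reaches_one(self):
        t, m = mcc_best_threshold([0.9, 0.7], [0.2, 0.1])
        assert m == 1.0 and 0.2 < t <= 0.7

    def test_no_signal_gives_zero(self):
        _, m = mcc_best_threshold([0.3, 0.6], [0.3, 0.6])
        assert m == 0.0

    def test_mcc_tie_breaks_toward_larger_threshold(self):
        # thresholds 0.9 and 0.2 both reach MCC 2/sqrt(12); the larger wins
        pos, neg = [0.9, 0.2], [0.5, 0.1]
        t, m = mcc_best_threshold(pos, neg)
        assert m == pytest.approx(2 / math.sqrt(12))
        assert t == 0.9


class TestMannWhitney:
    def test_textbook_example_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_no_evidence(self):
        res = mann_whitney_u([1.0, 2.0, 3.0, 4.0] * 5, [1.0, 2.0, 3.0, 4.0] * 5)
        assert res.p_value >= 0.99

    def test_empty_after_na_drop_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([np.nan], [1.0])

    def test_one_sided_less_than_two_sided_when_shifted(self):
        x, y = [5.0, 6, 7, 8], [1.0, 2, 3, 4]
        one = mann_whitney_u(x, y, sides="one")
        two = mann_whitney_u(x, y, sides="two")
        assert one.p_value == pytest.approx(two.p_value / 2)

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=10),
        st.lists(st.floats(0, 1), min_size=1, max_size=10),
    )
    def test_u_identity(self, xs, ys):
        u_xy = mann_whitney_u(xs, ys).statistic
        u_yx = mann_whitney_u(ys, xs).statistic
        assert u_xy + u_yx == pytest.approx(len(xs) * len(ys))

    def test_asymptotic_close_to_exact_without_ties(self, rng):
        # tie-free samples in the exact regime: the normal approximation
        # with continuity correction stays within 0.02 of the exact p
        for _ in range(50):
            n1, n2 = rng.integers(8, 16), rng.integers(8, 16)
            vals = rng.permutation(200)[: n1 + n2].astype(float)
            x, y = vals[:n1], vals[n1:]
            exact = mann_whitney_u(x, y).p_value
            approx = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(exact - approx) < 0.02


class TestPairedTTest:
    def test_two_pair_toy_closed_form(self):
        # diffs (0.4, 0.2): mean 0.3, sd 0.1414, t = 3 with df = 1;
        # one-sided p = 1/2 - arctan(3)/pi
        res = paired_one_sided_t_test([0.9, 0.8], [0.5, 0.6])
        assert res.statistic == pytest.approx(3.0)
        assert res.p_value == pytest.approx(0.5 - math.atan(3.0) / math.pi)

    def test_equal_inputs_give_p_one(self):
        res = paired_one_sided_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7], bonferroni_m=6)
        assert res.p_value == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        raw = paired_one_sided_t_test([0.6, 0.7, 0.65], [0.5, 0.6, 0.55]).p_value
        m3 = paired_one_sided_t_test([0.6, 0.7, 0.65], [0.5, 0.6, 0.55], bonferroni_m=3)
        assert m3.p_value == pytest.approx(min(1.0, raw * 3))
        huge = paired_one_sided_t_test([0.51, 0.49], [0.5, 0.5], bonferroni_m=1000)
        assert huge.p_value == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            paired_one_sided_t_test([0.5, 0.6], [0.5])


class TestGroupSummary:
    def test_single_value_median(self):
        table = _table({"REVEL": [0.42]}, ["1"])
        assert group_summary(table, "REVEL", "1").median == 0.42

    def test_median_and_polyphen_bins(self):
        table = _table({"PolyPhen2": [0.1, 0.2, 0.9]}, ["1", "1", "1"])
        s = group_summary(table, "PolyPhen2", "1")
        assert s.median == pytest.approx(0.2)
        assert s.bin_counts == {
            "benign": 1,
            "possibly damaging": 1,
            "probably damaging": 1,
        }

    def test_even_n_median_averages_middle_two(self):
        table = _table({"REVEL": [0.1, 0.2, 0.6, 0.9]}, ["1"] * 4)
        assert group_summary(table, "REVEL", "1").median == pytest.approx(0.4)

    def test_missing_counted_not_summarized(self):
        table = _table({"REVEL": [0.5, np.nan]}, ["1", "1"])
        s = group_summary(table, "REVEL", "1")
        assert (s.n, s.n_missing) == (1, 1)

    def test_unknown_tool_and_group_raise(self):
        table = _table({"REVEL": [0.5]}, ["1"])
        with pytest.raises(KeyError):
            group_summary(table, "NOSUCH", "1")
        with pytest.raises(KeyError):
            group_summary(table, "REVEL", "random")
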