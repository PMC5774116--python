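import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pilblind.blinding_index import (
    SCENARIO_IDS,
    STATUSES,
    BlindingAssessment,
    GuessTable,
    assess_blinding,
    assign_scenario,
    bang_bi,
    bi_confidence_interval,
    classify_bi,
    compare_bi_groups,
    scenario_for_statuses,
    scenario_frequency_grid,
)

counts = st.integers(min_value=0, max_value=200)


def tables(min_total=1):
    return st.builds(
        lambda arm, a, b, c: (arm, a, b, c),
        st.sampled_from(["real", "placebo"]),
        counts, counts, counts,
    ).filter(lambda t: t[1] + t[2] + t[3] >= min_total).map(lambda t: GuessTable(*t))


class TestBangBi:
    def test_all_correct_real_arm(self):
        assert bang_bi(GuessTable("real", 50, 0, 0)) == 1.0

    def test_placebo_arm_all_guess_real(self):
        assert bang_bi(GuessTable("placebo", 30, 0, 0)) == -1.0

    def test_balanced_guesses(self):
        assert bang_bi(GuessTable("real", 40, 40, 20)) == 0.0

    def test_hand_arithmetic(self):
        assert bang_bi(GuessTable("real", 60, 25, 15)) == pytest.approx(0.35)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            GuessTable("real", 0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            GuessTable("real", -1, 2, 3)

    @given(tables())
    def test_bounded(self, gt):
        assert -1.0 <= bang_bi(gt) <= 1.0

    @given(tables())
    def test_swapping_guess_counts_negates(self, gt):
        swapped = GuessTable(gt.arm, gt.n_guess_placebo, gt.n_guess_real, gt.n_dont_know)
        assert bang_bi(swapped) == pytest.approx(-bang_bi(gt))

    @given(tables())
    def test_relabeling_arm_negates(self, gt):
        other = "placebo" if gt.arm == "real" else "real"
        flipped = GuessTable(other, gt.n_guess_real, gt.n_guess_placebo, gt.n_dont_know)
        assert bang_bi(flipped) == pytest.approx(-bang_bi(gt))

    @given(tables().filter(lambda gt: gt.n_guess_real != gt.n_guess_placebo))
    def test_dont_know_shrinks_magnitude(self, gt):
        bigger = GuessTable(gt.arm, gt.n_guess_real, gt.n_guess_placebo, gt.n_dont_know + 5)
        assert abs(bang_bi(bigger)) < abs(bang_bi(gt))


class TestConfidenceInterval:
    def test_hand_arithmetic(self):
        se, lo, hi = bi_confidence_interval(GuessTable("real", 60, 25, 15))
        assert se == pytest.approx(0.0852936105461599, abs=1e-12)
        assert lo == pytest.approx(0.18282759521814085, abs=1e-9)
        assert hi == pytest.approx(0.5171724047818591, abs=1e-9)

    def test_degenerate_table(self):
        se, lo, hi = bi_confidence_interval(GuessTable("real", 50, 0, 0))
        assert se == 0.0
        assert (lo, hi) == (1.0, 1.0)

    def test_wider_level_nests(self):
        gt = GuessTable("placebo", 10, 20, 5)
        _, lo95, hi95 = bi_confidence_interval(gt, level=0.95)
        _, lo99, hi99 = bi_confidence_interval(gt, level=0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_truncation_flag(self):
        gt = GuessTable("real", 9, 0, 1)
        _, _, hi = bi_confidence_interval(gt)
        assert hi > 1.0
        _, _, hi_t = bi_confidence_interval(gt, truncate=True)
        assert hi_t == 1.0

    def test_bad_level(self):
        with pytest.raises(ValueError):
            bi_confidence_interval(GuessTable("real", 1, 1, 1), level=1.5)

    @given(tables())
    def test_ci_brackets_estimate(self, gt):
        a = assess_blinding(gt)
        assert a.ci_low <= a.bi <= a.ci_high


class TestClassify:
    @pytest.mark.parametrize(
        "bi,status",
        [
            (0.42, "unblinded"),
            (-0.16, "random_guess"),
            (-0.21, "opposite_guess"),
            (0.2, "unblinded"),
            (-0.2, "opposite_guess"),
            (0.19999, "random_guess"),
            (0.0, "random_guess"),
            (1.0, "unblinded"),
            (-1.0, "opposite_guess"),
        ],
    )
    def test_thresholds(self, bi, status):
        assert classify_bi(bi) == status

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_bi(1.5)

    def test_exhaustive_small_tables_vs_oracle(self):
        # brute-force oracle over every table with total <= 6
        for arm in ("real", "placebo"):
            for a, b, c in itertools.product(range(7), repeat=3):
                if not 0 < a + b + c <= 6:
                    continue
                gt = GuessTable(arm, a, b, c)
                bi = bang_bi(gt)
                if bi >= 0.2:
                    expected = "unblinded"
                elif bi <= -0.2:
                    expected = "opposite_guess"
                else:
                    expected = "random_guess"
                assert classify_bi(bi) == expected


class TestScenarios:
    @pytest.mark.parametrize(
        "exp,ctrl,sid",
        [
            ("random_guess", "random_guess", "S1"),
            ("random_guess", "opposite_guess", "S2"),
            ("random_guess", "unblinded", "S3"),
            ("unblinded", "unblinded", "S4"),
            ("unblinded", "opposite_guess", "S5"),
            ("unblinded", "random_guess", "S6"),
            ("opposite_guess", "opposite_guess", "S7"),
            ("opposite_guess", "random_guess", "S8"),
            ("opposite_guess", "unblinded", "S9"),
        ],
    )
    def test_grid_mapping(self, exp, ctrl, sid):
        assert assign_scenario(exp, ctrl).id == sid

    def test_bijection_and_roundtrip(self):
        seen = set()
        for exp, ctrl in itertools.product(STATUSES, repeat=2):
            sid = assign_scenario(exp, ctrl).id
            assert sid not in seen
            seen.add(sid)
            assert scenario_for_statuses(sid) == (exp, ctrl)
        assert seen == set(SCENARIO_IDS)

    def test_invalid_status(self):
        with pytest.raises(ValueError):
            assign_scenario("nope", "random_guess")

    def test_frequency_grid(self):
        grid = scenario_frequency_grid([("S1", "FD"), ("S5", "FD"), ("S5", "DD/MI")])
        assert grid.loc["S5", "FD_n"] == 1
        assert grid.loc["S5", "FD_pct"] == 50.0
        assert grid.loc["S5", "DD/MI_pct"] == 100.0
        assert grid["FD_n"].sum() == 2


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        res = compare_bi_groups([0.1, 0.2, 0.3, 0.15], [0.1, 0.2, 0.3, 0.15])
        assert res.p >= 0.05

    def test_forced_mannwhitney_exact(self):
        res = compare_bi_groups([1, 2, 3], [4, 5, 6], force="mannwhitney")
        assert res.test == "mann_whitney_u"
        # U for the first sample is 0; exact two-sided p over the 20 arrangements
        assert min(res.statistic, 9 - res.statistic) == 0.0
        assert res.p == pytest.approx(0.1)

    def test_t_branch_when_both_normal(self):
        rng = np.random.default_rng(7)
        res = compare_bi_groups(rng.normal(0, 1, 40), rng.normal(0, 1, 40))
        assert res.test == "independent_t"

    def test_mw_branch_when_nonnormal(self):
        rng = np.random.default_rng(7)
        a = np.exp(rng.normal(0, 2, 60))  # heavily skewed
        b = rng.normal(0, 1, 60)
        res = compare_bi_groups(a, b)
        assert res.test == "mann_whitney_u"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_bi_groups([1, 2], [1, 2, 3])

    def test_welch_flag_changes_statistic(self):
        a = [0.1, 0.5, 0.9, 0.2, 0.8]
        b = [0.31, 0.32, 0.33, 0.34]
        pooled = compare_bi_groups(a, b, force="t", welch=False)
        welch = compare_bi_groups(a, b, force="t", welch=True)
        assert pooled.p != welch.p

    def test_type_one_error_monte_carlo(self):
        # forced t-test on null normal samples rejects at ~alpha
        rng = np.random.default_rng(42)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0, 1, 30)
            if compare_bi_groups(a, b, force="t").p < 0.05:
                rejections += 1
        assert abs(rejections / n_sims - 0.05) < 0.02
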