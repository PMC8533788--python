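"""MRD categories, paired comparisons, association tests, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radarcyto.mrd_stats import (
    association_homogeneity_genetics,
    association_position_genetics,
    categorize_mrd,
    cohort_summary,
    compare_paired,
    quantify_blasts,
    round_half_up,
    two_proportion_z,
)
from radarcyto.synthetic_data import CaseRecord


def make_case(subtype, pos1=1, n_subclones=1, **kw):
    return CaseRecord(
        case_id="x", subtype=subtype, timepoint="diagnosis",
        blast_fraction=0.5, position_tube1=pos1, position_tube2=1,
        n_subclones=n_subclones, **kw)


class TestMRDCategories:
    @pytest.mark.parametrize("pct,expected", [
        (0.05, "FLR"), (0.0999, "FLR"), (0.1, "FMR"), (5.0, "FMR"),
        (9.99, "FMR"), (10.0, "FHR"), (85.0, "FHR"),
    ])
    def test_day15_boundaries(self, pct, expected):
        assert categorize_mrd(pct, "day15") == expected

    def test_day33_naming(self):
        assert categorize_mrd(0.05, "day33") == "lt0.1"
        assert categorize_mrd(0.5, "day33") == "mid"
        assert categorize_mrd(12.0, "day33") == "ge10"

    def test_quantify_blasts(self):
        nucleated = np.array([True] * 1000)
        blasts = np.zeros(1000, dtype=bool)
        blasts[:1] = True
        res = quantify_blasts(blasts, nucleated)
        assert res.blast_pct == pytest.approx(0.1)
        assert res.category == "FMR"

    def test_blasts_outside_nucleated_excluded(self):
        nucleated = np.array([True, True, False, False])
        blasts = np.array([True, False, True, False])
        res = quantify_blasts(blasts, nucleated)
        assert res.blast_pct == pytest.approx(50.0)

    def test_empty_nucleated_mask(self):
        with pytest.raises(ValueError, match="nucleated"):
            quantify_blasts(np.array([True]), np.array([False]))


def wilcoxon_oracle(d):
    """Exhaustive enumeration over all sign assignments of |d| ranks:
    exact two-sided p for the signed-rank statistic (no ties/zeros)."""
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if min(w, total - w) <= w_obs:
            count += 1
    return w_obs, count / 2 ** n


class TestComparePaired:
    def test_identical_vectors_p_one(self):
        x = np.arange(10.0)
        res = compare_paired(x, x)
        assert res.p_value == 1.0
        assert res.spearman_r == pytest.approx(1.0)

    def test_constant_vectors_flag_spearman_undefined(self):
        x = np.ones(8)
        res = compare_paired(x, x)
        assert res.p_value == 1.0
        assert res.spearman_undefined

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, 30)
        res = compare_paired(x, x + 5.0 + rng.normal(0, 0.1, 30))
        assert res.p_value < 0.01

    def test_wilcoxon_matches_enumeration_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([1.2, 1.1, 3.6, 3.2, 9.5, 5.7, 7.7, 8.4])
        d = y - x  # distinct |d|: the exact null distribution applies
        w_obs, p_exact = wilcoxon_oracle(d)
        res = stats.wilcoxon(y, x, method="exact")
        assert res.statistic == pytest.approx(w_obs)
        assert res.pvalue == pytest.approx(p_exact, abs=1e-12)
        # the routed comparison reports the same numbers when Shapiro
        # sends this pair down the Wilcoxon branch
        routed = compare_paired(x, y, alpha=0.99)  # force non-normal route
        assert routed.test_used == "wilcoxon"
        assert routed.statistic == pytest.approx(w_obs)

    def test_routing_follows_normality(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        res = compare_paired(x, x + rng.normal(0, 1, 40))
        assert (res.test_used == "paired_t") == (res.normality_p >= 0.05)

    def test_length_guard(self):
        with pytest.raises(ValueError):
            compare_paired([1, 2, 3], [1, 2, 3])


class TestAssociations:
    def test_diagonal_table_closed_form(self):
        cases = ([make_case("a", pos1=1)] * 10
                 + [make_case("b", pos1=2)] * 10)
        res = association_position_genetics(cases)
        # hand computation: all four expected counts are 5, chi2 = 20
        assert res.chi2 == pytest.approx(20.0, abs=1e-9)
        assert res.df == 1
        assert res.p_value < 0.001

    def test_uniform_positions_type_one_calibrated(self):
        rng = np.random.default_rng(0)
        n_shuffles = 100
        rejections = 0
        for _ in range(n_shuffles):
            cases = [
                make_case(st, pos1=int(rng.integers(1, 7)))
                for st in ["a"] * 30 + ["b"] * 30
            ]
            if association_position_genetics(cases).p_value < 0.05:
                rejections += 1
        rate = rejections / n_shuffles
        sd = np.sqrt(0.05 * 0.95 / n_shuffles)
        assert abs(rate - 0.05) <= 3 * sd

    def test_identical_proportions_z_zero(self):
        z, p = two_proportion_z(50, 100, 50, 100)
        assert z == 0.0 and p == 1.0

    def test_two_proportion_z_closed_form(self):
        # p1=0.6 (30/50), p2=0.3 (15/50); pooled p=0.45
        z, p = two_proportion_z(30, 50, 15, 50)
        pooled = 45 / 100
        se = np.sqrt(pooled * (1 - pooled) * (1 / 50 + 1 / 50))
        assert z == pytest.approx((0.6 - 0.3) / se, abs=1e-9)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_homogeneity_association_degenerate_table(self):
        cases = [make_case("a", n_subclones=1)] * 5
        with pytest.raises(ValueError, match="degenerate"):
            association_homogeneity_genetics(cases)

    def test_pairwise_rows_cover_subtype_pairs(self):
        cases = ([make_case("a", pos1=1)] * 5 + [make_case("b", pos1=2)] * 5
                 + [make_case("c", pos1=1)] * 5)
        res = association_position_genetics(cases)
        pairs = {(r[0], r[1]) for r in res.pairwise}
        assert pairs == {("a", "b"), ("a", "c"), ("b", "c")}


class TestCohortSummary:
    def test_counts_to_percentages(self):
        df = cohort_summary({"t(12;21)": 18, "B-other": 19, "rest": 35})
        assert df.loc["t(12;21)", "pct"] == 25.0
        assert df.loc["B-other", "pct"] == 26.4

    def test_zero_count_category(self):
        df = cohort_summary({"x": 0, "y": 72})
        assert df.loc["x", "pct"] == 0.0

    def test_explicit_total(self):
        df = cohort_summary({"FHR": 12}, total=72)
        assert df.loc["FHR", "pct"] == 16.7

    def test_labels_input(self):
        df = cohort_summary(["a", "a", "b", "b"])
        assert df.loc["a", "n"] == 2 and df.loc["a", "pct"] == 50.0

    def test_rounding_half_up(self):
        assert round_half_up(16.65, 1) == 16.7
        assert round_half_up(26.3888, 1) == 26.4
        assert round_half_up(2.5, 0) == 3.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary({})
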