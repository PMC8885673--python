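"""Paired analyte statistics, subgroup filtering, diet and T-cell helpers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coinflam import (
    AnalytePanel,
    SubjectVisitPair,
    exclude_subgroup,
    fiber_percent_of_iom_target,
    fold_change_of_means,
    mediator_change_table,
    memory_naive_ratio,
    paired_signed_rank,
    pearson_with_p,
    percent_reduction_of_means,
)
from coinflam.errors import CoinflamError, DegenerateTestError


def signed_rank_enumeration(diffs, alternative):
    """Exhaustive null over all sign patterns of the |difference| ranks."""
    d = np.asarray(diffs, float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            ranks[np.array(signs) == 1].sum()
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
    )
    p_ge = (ws >= w_obs).mean()
    p_le = (ws <= w_obs).mean()
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestPairedSignedRank:
    def test_all_increases_n6_exact(self):
        pre = np.zeros(6)
        post = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        _, p = paired_signed_rank(pre, post, alternative="greater")
        assert p == pytest.approx(1.0 / 64.0)

    def test_antisymmetric_differences_near_one(self):
        pre = np.zeros(6)
        post = np.array([1.0, -1.1, 2.0, -2.1, 3.0, -3.1])
        _, p = paired_signed_rank(pre, post)
        assert p > 0.8  # two-sided, null-centred up to rank discreteness

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_exhaustive_enumeration(self, alternative):
        rng = np.random.default_rng(21)
        for _ in range(10):
            d = rng.normal(0.4, 1.0, size=8)
            while len(np.unique(np.abs(d))) < 8 or (d == 0).any():
                d = rng.normal(0.4, 1.0, size=8)
            pre = rng.normal(size=8)
            post = pre + d
            _, p = paired_signed_rank(pre, post, alternative=alternative)
            assert p == pytest.approx(
                signed_rank_enumeration(d, alternative), abs=1e-12
            )

    def test_all_zero_differences_raise(self):
        x = np.arange(6, dtype=float)
        with pytest.raises(DegenerateTestError):
            paired_signed_rank(x, x.copy())


def make_panel(effects, n=10, seed=0, noise=0.01):
    """Panel with per-analyte multiplicative shifts and tight noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for analyte, shift_pct in effects.items():
        pre = 100.0 + rng.normal(0, 5, n)
        post = pre * (1 + shift_pct / 100.0) * (1 + rng.normal(0, noise, n))
        for i in range(n):
            rows.append((f"P{i}", "pre", analyte, pre[i], "pg/ml"))
            rows.append((f"P{i}", "post", analyte, post[i], "pg/ml"))
    return AnalytePanel(
        pd.DataFrame(rows, columns=["subject_id", "visit", "analyte",
                                    "value", "unit"])
    )


class TestMediatorChangeTable:
    def test_planted_reduction_retained_with_sign(self):
        panel = make_panel({"IL-12p40": -16.4, "flat": 0.0})
        table = mediator_change_table(panel)
        assert list(table["analyte"]) == ["IL-12p40"]
        assert table["percent_change"].iloc[0] == pytest.approx(-16.4, abs=1.5)

    def test_identical_values_excluded(self):
        rows = [
            (f"P{i}", v, "x", 50.0, "pg/ml")
            for i in range(8)
            for v in ("pre", "post")
        ]
        panel = AnalytePanel(
            pd.DataFrame(rows, columns=["subject_id", "visit", "analyte",
                                        "value", "unit"])
        )
        assert len(mediator_change_table(panel)) == 0

    def test_exact_boundary_excluded(self):
        # change of exactly 5.0% fails the strict |change| > 5 filter
        rows = []
        for i in range(8):
            rows.append((f"P{i}", "pre", "x", 100.0, "pg/ml"))
            rows.append((f"P{i}", "post", "x", 105.0, "pg/ml"))
        panel = AnalytePanel(
            pd.DataFrame(rows, columns=["subject_id", "visit", "analyte",
                                        "value", "unit"])
        )
        table = mediator_change_table(panel)
        assert len(table) == 0

    def test_row_count_monotone_in_thresholds(self):
        panel = make_panel(
            {"a": -20.0, "b": -8.0, "c": -6.0, "d": 3.0}, noise=0.05
        )
        loose = mediator_change_table(panel, 5.0, 0.5)
        tighter_change = mediator_change_table(panel, 10.0, 0.5)
        tighter_p = mediator_change_table(panel, 5.0, 0.01)
        assert len(tighter_change) <= len(loose)
        assert len(tighter_p) <= len(loose)

    def test_missing_visit_warns(self):
        rows = [(f"P{i}", "pre", "x", 10.0, "pg/ml") for i in range(6)]
        panel = AnalytePanel(
            pd.DataFrame(rows, columns=["subject_id", "visit", "analyte",
                                        "value", "unit"])
        )
        with pytest.warns(UserWarning, match="excluded"):
            table = mediator_change_table(panel)
        assert len(table) == 0


class TestMeanRatios:
    def test_butyrate_style_fold(self):
        assert fold_change_of_means(0.94, 1.32) == pytest.approx(1.40, abs=0.005)

    @pytest.mark.parametrize("pre,post,expected",
                             [(2.0, 2.0, 1.0), (2.0, 1.0, 0.5)])
    def test_fold_identities(self, pre, post, expected):
        assert fold_change_of_means(pre, post) == pytest.approx(expected)

    def test_percent_reduction(self):
        assert percent_reduction_of_means(119.0, 96.1) == pytest.approx(
            19.2, abs=0.05
        )
        assert percent_reduction_of_means(5.0, 5.0) == 0.0
        assert percent_reduction_of_means(100.0, 0.0) == 100.0

    def test_zero_pre_rejected(self):
        with pytest.raises(CoinflamError):
            fold_change_of_means(0.0, 1.0)


def subjects_with_aab(counts):
    return [
        SubjectVisitPair(f"P{i}", f"P{i}_pre", f"P{i}_post",
                         autoantibody_count=c)
        for i, c in enumerate(counts)
    ]


class TestExcludeSubgroup:
    def test_four_of_25_removed(self):
        counts = [2] * 4 + [0] * 19 + [1] * 2
        res = exclude_subgroup(subjects_with_aab(counts))
        assert len(res.retained) == 21
        assert len(res.removed_subject_ids) == 4

    def test_no_flagged_is_identity(self):
        subs = subjects_with_aab([0, 1, 0])
        res = exclude_subgroup(subs)
        assert res.retained == subs
        assert res.removed_subject_ids == []

    def test_all_flagged_warns_empty(self):
        with pytest.warns(UserWarning):
            res = exclude_subgroup(subjects_with_aab([2, 3]))
        assert res.retained == []

    def test_pure_filter_preserves_records(self):
        subs = subjects_with_aab([0, 2, 1])
        res = exclude_subgroup(subs)
        assert all(r in subs for r in res.retained)


class TestFiberStandardisation:
    @pytest.mark.parametrize(
        "fiber,kcal,expected",
        [(14.0, 1000.0, 100.0), (28.0, 1000.0, 200.0), (18.0, 1722.0, 74.7)],
    )
    def test_values(self, fiber, kcal, expected):
        assert fiber_percent_of_iom_target(fiber, kcal) == pytest.approx(
            expected, abs=0.05
        )

    def test_linear_in_fiber_inverse_in_kcal(self):
        base = fiber_percent_of_iom_target(10.0, 1500.0)
        assert fiber_percent_of_iom_target(30.0, 1500.0) == pytest.approx(3 * base)
        assert fiber_percent_of_iom_target(10.0, 3000.0) == pytest.approx(base / 2)

    def test_bad_kcal(self):
        with pytest.raises(CoinflamError):
            fiber_percent_of_iom_target(10.0, 0.0)


class TestTcellAndCorrelation:
    def test_memory_naive_ratio(self):
        assert memory_naive_ratio(30.0, 60.0) == pytest.approx(0.5)
        assert memory_naive_ratio(40.0, 40.0) == pytest.approx(1.0)
        with pytest.raises(CoinflamError):
            memory_naive_ratio(30.0, 0.0)

    def test_perfect_line(self):
        x = np.arange(10, dtype=float)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_t_transform_closed_form_n14(self):
        # construct vectors with r ~ 0.67 at n = 14 and verify p against
        # the t transform with n-2 df
        rng = np.random.default_rng(31)
        for _ in range(50):
            x = rng.normal(size=14)
            y = 0.67 * x + np.sqrt(1 - 0.67**2) * rng.normal(size=14)
            r, p = pearson_with_p(x, y)
            t = r * np.sqrt(12 / (1 - r**2))
            p_manual = 2 * stats.t.sf(abs(t), df=12)
            assert p == pytest.approx(p_manual, rel=1e-8)

    def test_r067_n14_p_near_reported(self):
        # the t transform at exactly r = 0.67, n = 14 gives p ~ 0.009,
        # consistent with the reported 0.008 within method tolerance
        r = 0.67
        t = r * np.sqrt(12 / (1 - r**2))
        p = 2 * stats.t.sf(t, df=12)
        assert p == pytest.approx(0.0087, abs=0.0015)

    def test_independent_large_n_small_r(self):
        rng = np.random.default_rng(32)
        x, y = rng.normal(size=(2, 10_000))
        r, _ = pearson_with_p(x, y)
        assert abs(r) < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(CoinflamError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
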