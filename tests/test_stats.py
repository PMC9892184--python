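"""Nonparametric battery vs brute-force enumeration oracles, plus
fold-change flagging and the physiological range check."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from cavbmonkey.stats import (
    fold_change_flag,
    flag_fold_table,
    friedman_dunn,
    mann_whitney_u,
    range_check,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------- oracles


def friedman_statistic_oracle(grid: np.ndarray) -> float:
    """Closed-form chi-square on within-row ranks (untied data)."""
    n, k = grid.shape
    ranks = np.vstack([rankdata(row) for row in grid])
    rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)


def wilcoxon_p_oracle(d: np.ndarray) -> float:
    """Exact two-sided p by enumeration of all sign assignments."""
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    tots = np.array(
        [
            sum(r for r, b in zip(ranks, bits) if b)
            for bits in itertools.product([0, 1], repeat=len(d))
        ]
    )
    p_lo = np.mean(tots <= obs + 1e-9)
    p_hi = np.mean(tots >= obs - 1e-9)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def mannwhitney_p_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by direct evaluation over all group labelings,
    counting labelings at least as deviant from the null mean."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    mu = na * (n - na) / 2.0

    def u_of(sel):
        ga = pooled[list(sel)]
        gb = np.delete(pooled, list(sel))
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)

    u_obs = u_of(range(na))
    dev = abs(u_obs - mu)
    hits = sum(
        1
        for sel in itertools.combinations(range(n), na)
        if abs(u_of(sel) - mu) >= dev - 1e-12
    )
    return hits / comb(n, na)


# ---------------------------------------------------------------- friedman


class TestFriedman:
    def test_identical_columns_statistic_zero(self):
        grid = pd.DataFrame({c: [5.0, 7.0, 9.0, 2.0] for c in "abc"})
        # perfectly tied grids are degenerate for the chi-square; jitter-free
        # equality means all ranks tie -> statistic 0 via tie correction
        res = friedman_dunn(grid + np.arange(4)[:, None] * 0.0, "a")
        assert res.statistic == pytest.approx(0.0)
        assert not res.comparisons["significant"].any()

    @pytest.mark.parametrize("seed", range(6))
    def test_statistic_matches_rank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.normal(size=(4, 3))
        df = pd.DataFrame(grid, columns=["t0", "t1", "t2"])
        res = friedman_dunn(df, "t0")
        assert res.statistic == pytest.approx(friedman_statistic_oracle(grid))

    def test_monotone_grid_extreme_ranks(self):
        rng = np.random.default_rng(1)
        base = np.sort(rng.uniform(1, 10, size=(10, 3)), axis=1)
        df = pd.DataFrame(base, columns=["a", "b", "c"])
        res = friedman_dunn(df, "a")
        # every animal ranks 1,2,3 -> rank means exactly 1, 2, 3
        assert res.rank_means.tolist() == [1.0, 2.0, 3.0]
        comp = res.comparisons.set_index("timepoint")
        assert comp.loc["c", "significant"]
        assert comp.loc["c", "p_adj"] < comp.loc["b", "p_adj"]

    def test_listwise_deletion(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan, 4.0], "b": [2.0, 3.0, 1.0, 5.0], "c": [3.0, 4.0, 2.0, 6.0]}
        )
        res = friedman_dunn(df, "a")
        assert res.n == 3

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]})
        with pytest.raises(ValueError):
            friedman_dunn(df, "a")

    def test_missing_reference_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            friedman_dunn(df, "z")


# ---------------------------------------------------------------- wilcoxon


class TestWilcoxon:
    def test_uniform_shift_extreme_p(self):
        d = np.arange(1, 9) + 0.01 * np.arange(8)  # untied positive diffs
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(2.0 / 2**8)

    def test_antisymmetric_pairs_not_significant(self):
        d = np.array([-3.0, -1.9, -1.0, 1.1, 2.0, 3.1])
        _, p = wilcoxon_signed_rank(d)
        assert p > 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.4, 1.0, size=10), 3)
        d = d[d != 0]
        if np.unique(np.abs(d)).size < d.size:
            d = d + rng.normal(0, 1e-6, d.size)  # break accidental ties
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(wilcoxon_p_oracle(d), abs=1e-12)

    def test_pairs_interface_drops_zero_differences(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 1.0, 1.0, 1.0])
        w, p = wilcoxon_signed_rank(x, y)  # one zero difference dropped
        _, p_direct = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert p == pytest.approx(p_direct)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(5))


# ------------------------------------------------------------ mannwhitney


class TestMannWhitney:
    def test_complete_separation_4v6(self):
        u, p = mann_whitney_u([10, 11, 12, 13], [1, 2, 3, 4, 5, 6])
        assert u in (0.0, 24.0)
        assert p == pytest.approx(2 * 24 * 720 / 3628800)  # 2*(4!6!)/10!

    def test_identical_groups_midpoint_u(self):
        u, _ = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)  # n_a*n_b/2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_labeling_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = np.round(rng.normal(0.5, 1.0, 4), 1)  # rounding induces ties
        b = np.round(rng.normal(0.0, 1.0, 6), 1)
        u, p = mann_whitney_u(a, b)
        assert p == pytest.approx(mannwhitney_p_oracle(a, b), abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        a = np.array([0.5, 1.2, 3.1, 4.0])
        b = np.array([0.1, 0.9, 2.0, 2.5, 3.5, 5.0])
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(np.exp(a), np.exp(b))
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_shift_invariance(self):
        a, b = np.array([1.0, 2.0, 5.0]), np.array([0.5, 3.0, 4.0, 6.0])
        _, p1 = mann_whitney_u(a, b)
        _, p2 = mann_whitney_u(a + 100.0, b + 100.0)
        assert p1 == pytest.approx(p2)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        _, p = mann_whitney_u(a, b)
        assert 0.0 < p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


# ------------------------------------------------------------- fold change


class TestFoldChange:
    @pytest.mark.parametrize(
        "fold,flagged",
        [(2.00, True), (1.0, False), (0.47, True), (1.99, False), (0.50, True), (0.51, False)],
    )
    def test_flag_boundaries(self, fold, flagged):
        fc = fold_change_flag(fold, 1.0, gene="X")
        assert fc.flagged == flagged

    def test_flag_applies_to_rounded_report_value(self):
        assert fold_change_flag(1.995, 1.0).flagged  # rounds to 2.00
        assert not fold_change_flag(0.5051, 1.0).flagged  # rounds to 0.51

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            fold_change_flag(0.0, 1.0)

    def test_packaged_expression_table_flags(self):
        from cavbmonkey.scoring import _fixture

        df = flag_fold_table(_fixture("table4_fold_changes.csv"))
        by_gene = df.set_index(["gene", "probe"])
        assert by_gene.loc[("KCNJ2", 1), "flagged"]
        assert by_gene.loc[("IFI27", 1), "flagged"]
        assert by_gene.loc[("CACNA1D", 1), "flagged"]
        assert not by_gene.loc[("KCNH2", 1), "flagged"]
        # 16 starred entries in the published expression summary
        assert int(df["flagged"].sum()) == 16


# ------------------------------------------------------------- range check


class TestRangeCheck:
    def test_published_aldosterone_example(self):
        assert range_check(25.3, 10.0, 20.0) == "outside-high"

    def test_boundary_is_within(self):
        assert range_check(20.0, 10.0, 20.0) == "within"
        assert range_check(10.0, 10.0, 20.0) == "within"

    def test_published_anp_basal_within(self):
        assert range_check(7.23, 2.0, 44.0) == "within"

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            range_check(1.0, 5.0, 5.0)
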