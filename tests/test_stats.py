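"""Rank tests against enumeration oracles, BCa internals, min-P adjustment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cispairs.stats import (
    bca_bootstrap_median_diff,
    bca_endpoint_probs,
    mann_whitney,
    resampling_adjust,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(diffs):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    )
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def brute_force_mw_p(x, y):
    """Two-sided exact p by enumerating all C(n+m, n) label arrangements."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array(
        [
            ranks[list(idx)].sum() - n * (n + 1) / 2
            for idx in itertools.combinations(range(len(combined)), n)
        ]
    )
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestSignedRank:
    def test_all_positive_n5(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.statistic == 15.0
        assert res.mode == "exact"
        assert res.p_raw == pytest.approx(2 / 32)

    def test_balanced_pair_p_one(self):
        res = wilcoxon_signed_rank([3, -3])
        assert res.p_raw == pytest.approx(1.0)

    def test_zeros_dropped_with_flag(self):
        res = wilcoxon_signed_rank([0, 0, 1, 2, 3])
        assert res.n == 3 and "zero differences dropped" in res.flag

    def test_all_zero_undefined(self):
        assert not wilcoxon_signed_rank([0.0, 0.0]).defined

    @pytest.mark.parametrize("n", range(1, 8))
    def test_exact_matches_enumeration_small_n(self, n):
        base = np.arange(1.0, n + 1)
        for signs in itertools.product([1, -1], repeat=n):
            d = base * np.array(signs)
            res = wilcoxon_signed_rank(d)
            assert res.mode == "exact"
            assert res.p_raw == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_approximate_converges_to_exact_at_n40(self):
        # beyond the exact-mode cutoff the normal approximation should sit
        # within 0.005 of the dynamic-programming exact tail on tie-free data
        from cispairs.stats import _signed_rank_counts, _two_sided_from_counts

        rng = np.random.default_rng(0)
        for _ in range(5):
            d = rng.normal(0.2, 1.0, size=45)
            res = wilcoxon_signed_rank(d)
            assert res.mode == "approximate"
            exact_p = _two_sided_from_counts(_signed_rank_counts(45), res.statistic)
            assert abs(res.p_raw - exact_p) < 0.005


class TestMannWhitney:
    def test_separated_groups_2x2(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.mode == "exact"
        assert res.p_raw == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.5, 3.5], [1.0, 2.5, 3.5])
        assert res.p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize("n,m", [(2, 3), (4, 4), (5, 3), (7, 6)])
    def test_exact_matches_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        x = rng.normal(0.8, 1, n)
        y = rng.normal(0, 1, m)
        res = mann_whitney(x, y)
        assert res.mode == "exact"
        assert res.p_raw == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_approximate_converges_to_exact_beyond_cutoff(self):
        from cispairs.stats import _mann_whitney_counts, _two_sided_from_counts

        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(0.3, 1, 25)
            y = rng.normal(0.0, 1, 25)
            res = mann_whitney(x, y)
            assert res.mode == "approximate"  # 625 > exact cutoff
            exact_p = _two_sided_from_counts(_mann_whitney_counts(25, 25), res.statistic)
            assert abs(res.p_raw - exact_p) < 0.005

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBcaBootstrap:
    def test_endpoint_probs_reduce_to_percentile(self):
        lo, hi = bca_endpoint_probs(0.0, 0.0, 0.95)
        assert lo == pytest.approx(0.025, abs=1e-12)
        assert hi == pytest.approx(0.975, abs=1e-12)
        lo90, hi90 = bca_endpoint_probs(0.0, 0.0, 0.90)
        assert (lo90, hi90) == pytest.approx((0.05, 0.95), abs=1e-12)

    def test_constant_groups_degenerate_interval(self):
        ci = bca_bootstrap_median_diff([5.0] * 8, [5.0] * 8, B=999, seed=0)
        assert (ci.estimate, ci.lower, ci.upper) == (0.0, 0.0, 0.0)
        assert "degenerate" in ci.flag

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        a = bca_bootstrap_median_diff(x, y, B=999, seed=77)
        b = bca_bootstrap_median_diff(x, y, B=999, seed=77)
        assert (a.lower, a.upper, a.z0, a.a) == (b.lower, b.upper, b.z0, b.a)

    def test_interval_brackets_estimate_and_truth_typically(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(1, 1, 60), rng.normal(0, 1, 60)
        ci = bca_bootstrap_median_diff(x, y, B=2000, seed=4)
        assert ci.lower <= ci.estimate <= ci.upper
        assert ci.upper - ci.lower < 2.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            bca_bootstrap_median_diff([1, 2, 3], [1, 2, 3, 4, 5], seed=0)

    def test_paired_mode_requires_equal_sizes(self):
        with pytest.raises(ValueError):
            bca_bootstrap_median_diff(np.arange(6), np.arange(7), paired=True, seed=0)


class TestResamplingAdjust:
    def test_single_hypothesis_adjusted_close_to_raw(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame({"g1": rng.normal(0.5, 1, 30)})
        group = ["a"] * 15 + ["b"] * 15
        data.iloc[15:, 0] -= 0.5
        (res,) = resampling_adjust(data, group=group, test="mann_whitney", B=2000, seed=6)
        tol = 2 * math.sqrt(res.p_raw * (1 - res.p_raw) / 2000) + 0.02
        assert abs(res.p_adjusted - res.p_raw) < tol

    def test_duplicated_features_incur_no_penalty(self):
        rng = np.random.default_rng(7)
        col = rng.normal(0, 1, 40)
        col[:20] += 0.8
        data = pd.DataFrame({f"g{i}": col for i in range(6)})
        group = ["a"] * 20 + ["b"] * 20
        results = resampling_adjust(data, group=group, B=2000, seed=8)
        for res in results:
            tol = 2 * math.sqrt(max(res.p_raw, 1e-4) * (1 - res.p_raw) / 2000) + 0.02
            assert abs(res.p_adjusted - res.p_raw) < tol

    def test_independent_null_features_match_closed_form(self):
        # for m independent features, adjusted p ~= 1 - (1 - raw)^m
        rng = np.random.default_rng(9)
        m, n = 10, 40
        data = pd.DataFrame(rng.normal(size=(n, m)), columns=[f"g{i}" for i in range(m)])
        group = ["a"] * 20 + ["b"] * 20
        results = resampling_adjust(data, group=group, B=4000, seed=10)
        for res in results:
            if res.p_raw < 0.2:
                expected = 1 - (1 - res.p_raw) ** m
                assert res.p_adjusted == pytest.approx(expected, abs=0.05)

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(rng.normal(size=(30, 8)))
        data.iloc[:15, 0] += 1.5
        data.iloc[:15, 1] += 0.5
        results = resampling_adjust(data, group=["a"] * 15 + ["b"] * 15, B=1000, seed=12)
        by_raw = sorted(results, key=lambda r: r.p_raw)
        adj = [r.p_adjusted for r in by_raw]
        assert adj == sorted(adj)

    def test_signed_rank_mode(self):
        rng = np.random.default_rng(13)
        data = pd.DataFrame(
            {"up": rng.normal(1.0, 1, 30), "null": rng.normal(0, 1, 30)}
        )
        res = {r.feature_id: r for r in resampling_adjust(data, test="signed_rank", B=2000, seed=14)}
        assert res["up"].p_raw < 0.01
        assert res["up"].p_adjusted >= res["up"].p_raw - 0.01
        assert res["null"].p_raw > 0.05

    def test_adjusted_never_much_below_raw(self):
        rng = np.random.default_rng(15)
        data = pd.DataFrame(rng.normal(size=(24, 5)))
        results = resampling_adjust(data, group=["a"] * 12 + ["b"] * 12, B=1000, seed=16)
        for r in results:
            assert r.p_adjusted >= r.p_raw - 0.05


class TestBatchAdjust:
    def test_long_format_round_trip(self):
        from cispairs.stats import batch_adjust

        rng = np.random.default_rng(20)
        rows = []
        for j in range(4):
            vals = rng.normal(0.0, 1, 24)
            if j == 0:
                vals[:12] += 1.8  # group "a" shifted for the first feature
            for i, v in enumerate(vals):
                rows.append(
                    {"feature": f"g{j}", "sample": f"s{i}",
                     "group": "a" if i < 12 else "b", "value": v}
                )
        long = pd.DataFrame(rows)
        out = batch_adjust(long, test="mann_whitney", B=1000, seed=3)
        assert list(out.columns[:2]) == ["feature", "method"]
        assert set(out.feature) == {"g0", "g1", "g2", "g3"}
        assert {"mode", "B", "seed"} <= set(out.columns)
        g0 = out.set_index("feature").loc["g0"]
        assert g0.p_raw < 0.05 and g0.p_adjusted >= g0.p_raw - 0.01

    def test_missing_columns_rejected(self):
        from cispairs.stats import batch_adjust

        with pytest.raises(ValueError, match="missing columns"):
            batch_adjust(pd.DataFrame({"feature": [], "value": []}))
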