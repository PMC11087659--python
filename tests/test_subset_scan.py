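import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import traitscan as ts
from traitscan.subset_scan import _hc_F


class TestAlphaGrid:
    def test_default_bounds_p50(self):
        g = ts.make_alpha_grid(50)
        assert g.length == 200
        assert g.alphas[0] == pytest.approx(0.001, rel=1e-12)
        assert g.alphas[-1] == pytest.approx(0.05, rel=1e-12)

    def test_geometric_spacing(self):
        g = ts.make_alpha_grid(754)
        ratios = g.alphas[1:] / g.alphas[:-1]
        assert np.max(np.abs(ratios - ratios[0])) < 1e-10

    def test_p1_degenerate(self):
        g = ts.make_alpha_grid(1)
        assert np.allclose(g.alphas, 0.05)

    def test_gamma_of_005(self):
        g = ts.make_alpha_grid(20)
        assert g.gammas[-1] == pytest.approx(1.959964, abs=1e-6)

    def test_gammas_strictly_decreasing(self):
        g = ts.make_alpha_grid(100)
        assert np.all(np.diff(g.gammas) < 0)

    def test_bad_bounds(self):
        with pytest.raises(ts.DomainError):
            ts.make_alpha_grid(10, lower=0.1, upper=0.05)

    def test_grid_hash_stable(self):
        assert ts.make_alpha_grid(10).grid_hash == ts.make_alpha_grid(10).grid_hash
        assert ts.make_alpha_grid(10).grid_hash != ts.make_alpha_grid(11).grid_hash


class TestHcScore:
    def test_all_below_threshold(self):
        p_star = np.array([0.01, 0.02, 0.03, 0.04])
        got = ts.hc_score(p_star, 0.05, [0, 1, 2, 3])
        assert got == pytest.approx(np.sqrt(76), rel=1e-12)

    def test_partial_count(self):
        got = ts.hc_score(np.array([0.05, 0.5]), 0.1, [0, 1])
        assert got == pytest.approx(0.8 / np.sqrt(0.18), rel=1e-12)

    def test_single_empty_count(self):
        a = 0.2
        got = ts.hc_score(np.array([0.9]), a, [0])
        assert got == pytest.approx(-np.sqrt(a / (1 - a)), rel=1e-12)

    def test_strict_inequality_at_boundary(self):
        # p* exactly equal to alpha is not counted
        assert ts.hc_score(np.array([0.05]), 0.05, [0]) < 0

    def test_empty_subset_rejected(self):
        with pytest.raises(ts.DomainError):
            ts.hc_score(np.array([0.5]), 0.05, [])


class TestLtssHc:
    def test_single_strong_signal(self, grid8):
        p_star = np.array([1e-6, 0.5, 0.6, 0.7])
        grid = ts.make_alpha_grid(4)
        res = ts.ltss_maximize_hc(p_star, grid)
        assert list(res.subset) == [0]
        oracle = ts.exhaustive_scan(p_star, grid, "hc")
        assert res.statistic == oracle.statistic

    def test_no_signal_negative(self):
        grid = ts.make_alpha_grid(4)
        res = ts.ltss_maximize_hc(np.full(4, 0.5), grid)
        assert res.statistic < 0 and res.k == 1

    def test_matches_exhaustive_random(self, grid8, rng):
        for _ in range(150):
            p_star = ts.whitened_pvalues(rng.standard_normal(8) * rng.uniform(0.5, 2))
            a = ts.ltss_maximize_hc(p_star, grid8)
            b = ts.exhaustive_scan(p_star, grid8, "hc")
            assert a.statistic == b.statistic

    def test_huge_signal_selects_singleton(self, rng):
        # independent traits, one p* = 1e-12, rest uniform
        grid = ts.make_alpha_grid(10)
        p_star = np.concatenate([[1e-12], rng.uniform(0.2, 1.0, 9)])
        res = ts.ltss_maximize_hc(p_star, grid)
        assert list(res.subset) == [0] and res.grid_index == 0

    def test_permutation_invariance(self, rng):
        grid = ts.make_alpha_grid(6)
        p_star = ts.whitened_pvalues(rng.standard_normal(6))
        perm = rng.permutation(6)
        a = ts.ltss_maximize_hc(p_star, grid)
        b = ts.ltss_maximize_hc(p_star[perm], grid)
        assert a.statistic == b.statistic
        assert sorted(perm[b.subset]) == sorted(a.subset)

    def test_monotone_in_selected_pvalue(self, rng):
        grid = ts.make_alpha_grid(6)
        for _ in range(30):
            p_star = ts.whitened_pvalues(rng.standard_normal(6))
            res = ts.ltss_maximize_hc(p_star, grid)
            j = int(res.subset[0])
            p2 = p_star.copy()
            p2[j] *= 0.5
            assert ts.ltss_maximize_hc(p2, grid).statistic >= res.statistic

    def test_batch_matches_single(self, rng):
        grid = ts.make_alpha_grid(7)
        P = ts.whitened_pvalues(rng.standard_normal(7 * 60)).reshape(60, 7)
        H = ts.hc_max_batch(P, grid)
        singles = np.array([ts.ltss_maximize_hc(P[i], grid).statistic for i in range(60)])
        assert np.array_equal(H, singles)


class TestLtssTc:
    def test_single_strong_signal(self, table5, grid5):
        z = np.array([4.0, 0.1, 0.1, 0.1, 0.1])
        res = ts.ltss_maximize_tc(z, grid5, table5)
        assert list(res.subset) == [0]
        oracle = ts.exhaustive_scan(z, grid5, "tc", table=table5)
        assert res.statistic == oracle.statistic

    def test_all_zero(self, grid5, table5):
        res = ts.ltss_maximize_tc(np.zeros(5), grid5, table5)
        assert res.statistic == 0.0 and res.k == 1 and res.grid_index == 0

    def test_matches_exhaustive_random(self, grid8, table8, rng):
        for _ in range(150):
            z = rng.standard_normal(8) * rng.uniform(0.5, 2)
            a = ts.ltss_maximize_tc(z, grid8, table8)
            b = ts.exhaustive_scan(z, grid8, "tc", table=table8)
            assert a.statistic == b.statistic

    def test_monotone_in_selected_z(self, grid5, table5, rng):
        for _ in range(20):
            z = rng.standard_normal(5) * 1.5
            res = ts.ltss_maximize_tc(z, grid5, table5)
            j = int(res.subset[0])
            z2 = z.copy()
            z2[j] *= 1.5
            assert ts.ltss_maximize_tc(z2, grid5, table5).statistic >= res.statistic

    def test_batch_matches_single(self, grid8, table8, rng):
        Z = rng.standard_normal((60, 8))
        H = ts.tc_max_batch(Z, grid8, table8)
        singles = np.array([ts.ltss_maximize_tc(Z[i], grid8, table8).statistic
                            for i in range(60)])
        assert np.array_equal(H, singles)


class TestExhaustive:
    def test_p1_single_subset(self):
        grid = ts.make_alpha_grid(1)
        res = ts.exhaustive_scan(np.array([0.3]), grid, "hc")
        assert list(res.subset) == [0]

    def test_p_over_cap_refused(self):
        grid = ts.make_alpha_grid(21)
        with pytest.raises(ts.DomainError, match="refuses"):
            ts.exhaustive_scan(np.full(21, 0.5), grid, "hc")

    def test_batch_matches_scalar(self, grid8, table8, rng):
        Z = rng.standard_normal((10, 8))
        Hb = ts.exhaustive_max_batch(Z, grid8, "tc", table8)
        for i in range(10):
            assert ts.exhaustive_scan(Z[i], grid8, "tc", table=table8).statistic == Hb[i]


class TestPhewas:
    def test_paper_threshold(self):
        # 754 traits x 6 SNPs at overall level 0.05
        z = np.zeros(754)
        _, _, thr = ts.phewas_minp(z, n_tests=754 * 6)
        assert thr == pytest.approx(1.105e-5, rel=1e-3)

    def test_null_no_rejection(self):
        sel, reject, _ = ts.phewas_minp(np.zeros(10), n_tests=10)
        assert not reject and len(sel) == 0

    def test_huge_signal_selected(self):
        z = np.zeros(20)
        z[7] = 10.0  # p ~ 1.5e-23 << 1e-5
        sel, reject, _ = ts.phewas_minp(z, n_tests=5000)
        assert reject and list(sel) == [7]

    def test_n_tests_must_cover_traits(self):
        with pytest.raises(ts.DomainError):
            ts.phewas_minp(np.zeros(10), n_tests=5)


class TestBonferroni:
    def test_values(self):
        assert ts.bonferroni_level(0.05, 6) == pytest.approx(0.05 / 6)
        assert ts.bonferroni_level(0.05, 2) == 0.025

    def test_domain(self):
        with pytest.raises(ts.DomainError):
            ts.bonferroni_level(0.05, 0)


@given(st.integers(min_value=1, max_value=30), st.floats(min_value=0.001, max_value=0.5))
@settings(max_examples=50, deadline=None)
def test_hc_F_zero_mean_unit_scale(N, alpha):
    # F standardizes a Binomial(k, alpha) count at k = N: mean alpha*k, var k a(1-a)
    k = N
    val = float(_hc_F(N, k, alpha))
    assert val == pytest.approx((N - alpha * k) / np.sqrt(k * alpha * (1 - alpha)))
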