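import numpy as np
import pytest
from scipy import stats

import traitscan as ts
from traitscan.significance import (
    combined_test,
    hc_pvalue_analytic,
    hc_pvalue_analytic_many,
    mc_pvalue,
    simulate_null,
)


@pytest.fixture(scope="module")
def small_null():
    grid = ts.make_alpha_grid(5)
    table = ts.get_tc_table(grid, n_draws=20_000)
    return grid, table, simulate_null(5, grid, B=2000, seed=42, table=table)


class TestMcPvalue:
    def test_above_all(self):
        draws = np.sort(np.arange(999, dtype=float))
        assert mc_pvalue(1e9, draws) == pytest.approx(1 / 1000)

    def test_at_minimum(self):
        draws = np.sort(np.arange(100, dtype=float))
        assert mc_pvalue(0.0, draws) == 1.0

    def test_median_near_half(self, rng):
        draws = np.sort(rng.standard_normal(100_001))
        assert mc_pvalue(float(np.median(draws)), draws) == pytest.approx(0.5, abs=0.01)

    def test_eq13_is_complement_fraction(self):
        draws = np.sort(np.arange(10, dtype=float))
        # literal printed form counts null draws strictly below the observed value
        assert mc_pvalue(7.5, draws, convention="eq13") == pytest.approx(0.8)


class TestSimulateNull:
    def test_seeded_determinism(self, small_null):
        grid, table, null = small_null
        again = simulate_null(5, grid, B=2000, seed=42, table=table)
        assert np.array_equal(null.joint_hc, again.joint_hc)
        assert np.array_equal(null.joint_tc, again.joint_tc)

    def test_self_consistency_ks(self, small_null):
        grid, table, null = small_null
        other = simulate_null(5, grid, B=2000, seed=43, table=table)
        d = stats.ks_2samp(null.h_hc, other.h_hc).statistic
        assert d < 0.05

    def test_disk_cache_round_trip(self, small_null, tmp_path):
        grid, table, null = small_null
        fresh = simulate_null(5, grid, B=500, seed=7, table=table, cache_dir=tmp_path)
        from traitscan.significance import _NULL_MEMO

        _NULL_MEMO.clear()
        cached = simulate_null(5, grid, B=500, seed=7, table=table, cache_dir=tmp_path)
        assert np.array_equal(fresh.joint_tc, cached.joint_tc)

    def test_json_round_trip(self, small_null, tmp_path):
        grid, table, null = small_null
        null.to_json(tmp_path / "null.json")
        back = ts.NullDistribution.from_json(tmp_path / "null.json")
        assert back.p_traits == 5 and back.B == null.B
        assert np.array_equal(back.h_hc, null.h_hc)

    def test_small_B_rejected(self, small_null):
        grid, table, _ = small_null
        with pytest.raises(ts.DomainError):
            simulate_null(5, grid, B=50, seed=0, table=table)


class TestHcAnalytic:
    def test_infinities(self):
        grid = ts.make_alpha_grid(10)
        assert hc_pvalue_analytic(-np.inf, 10, grid) == 1.0
        assert hc_pvalue_analytic(np.inf, 10, grid) == 0.0

    def test_below_floor_is_one(self):
        grid = ts.make_alpha_grid(10)
        assert hc_pvalue_analytic(-10.0, 10, grid) == 1.0

    def test_matches_mc(self, small_null):
        grid, table, null = small_null
        for q in (0.5, 0.9, 0.95):
            h = float(np.quantile(null.h_hc, q))
            mc = mc_pvalue(h, null.h_hc)
            an = hc_pvalue_analytic(h, 5, grid)
            se = np.sqrt(mc * (1 - mc) / null.B)
            assert abs(an - mc) < 4 * se + 2 / null.B

    def test_many_matches_scalar(self, small_null):
        grid, table, null = small_null
        hs = null.joint_hc[:50]
        many = hc_pvalue_analytic_many(hs, 5, grid)
        assert many[7] == hc_pvalue_analytic(float(hs[7]), 5, grid)

    def test_monotone_in_h(self):
        grid = ts.make_alpha_grid(8)
        hs = np.linspace(-0.5, 25, 40)
        pv = [hc_pvalue_analytic(float(h), 8, grid) for h in hs]
        assert np.all(np.diff(pv) <= 1e-12)


class TestCombined:
    def test_tie_goes_to_hc(self, small_null):
        grid, table, null = small_null
        z = np.zeros(5)
        res = ts.scan_and_test(z, np.eye(5), grid=grid, null=null, table=table)
        if res.p_hc == res.p_tc:
            assert res.winner == "hc"

    def test_extreme_signal_floor(self, small_null):
        grid, table, null = small_null
        z = np.array([12.0, 0.1, -0.2, 0.05, 0.3])
        res = ts.scan_and_test(z, np.eye(5), grid=grid, null=null, table=table)
        assert res.p_combined == pytest.approx(1.0 / (null.B + 1))
        assert res.p_tc == pytest.approx(1.0 / (null.B + 1))

    def test_p_combined_floor_invariant(self, small_null, rng):
        grid, table, null = small_null
        for _ in range(10):
            z = rng.standard_normal(5)
            res = ts.scan_and_test(z, np.eye(5), grid=grid, null=null, table=table)
            assert res.p_combined >= 1.0 / (null.B + 1)

    def test_grid_mismatch_rejected(self, small_null):
        grid, table, null = small_null
        other_grid = ts.make_alpha_grid(6)
        with pytest.raises(ts.ValidationError):
            ts.scan_and_test(np.zeros(6), np.eye(6), grid=other_grid, null=null)

    def test_combined_returns_consistent_subset(self, small_null, rng):
        grid, table, null = small_null
        z = rng.standard_normal(5) * 1.5
        res = ts.scan_and_test(z, np.eye(5), grid=grid, null=null, table=table)
        expect = res.s_hc if res.winner == "hc" else res.s_tc
        assert np.array_equal(res.s_combined, expect)


class TestScanAndTest:
    def test_null_input_not_significant(self, small_null):
        grid, table, null = small_null
        res = ts.scan_and_test(np.zeros(5), np.eye(5), grid=grid, null=null, table=table)
        assert res.p_combined > 0.5 and res.p_hc > 0.5 and res.p_tc > 0.5

    def test_determinism(self, small_null, rng):
        grid, table, null = small_null
        z = rng.standard_normal(5)
        a = ts.scan_and_test(z, np.eye(5), grid=grid, null=null, table=table)
        b = ts.scan_and_test(z, np.eye(5), grid=grid, null=null, table=table)
        assert a.to_dict() == b.to_dict()

    def test_zvector_and_trait_reindexing(self, small_null, rng):
        grid, table, null = small_null
        ids = [f"T{j+1}" for j in range(5)]
        zv = ts.ZVector("rs1", ids, rng.standard_normal(5))
        R = ts.repair_psd(np.eye(5), trait_ids=list(reversed(ids)))
        res = ts.scan_and_test(zv, R, grid=grid, null=null, table=table)
        assert res.variant_id == "rs1" and res.trait_ids == ids

    def test_calibration_small(self, small_null):
        # rejection rate at 0.05 under H0; loose envelope for a quick check
        grid, table, null = small_null
        rng = np.random.default_rng(99)
        M, B = 2000, null.B
        Z = rng.standard_normal((M, 5))
        P = 2.0 * stats.norm.sf(np.abs(Z))
        Hh = ts.hc_max_batch(P, grid)
        Ht = ts.tc_max_batch(Z, grid, table)
        ph = hc_pvalue_analytic_many(Hh, 5, grid)
        pt = (B - np.searchsorted(null.h_tc, Ht, side="left") + 1.0) / (B + 1.0)
        comb_null = np.sort(np.minimum(null.pp_hc(grid), null.pp_tc()))
        pc = (np.searchsorted(comb_null, np.minimum(ph, pt), side="right") + 1.0) / (B + 1.0)
        for pv in (ph, pt, pc):
            assert 0.03 < np.mean(pv <= 0.05) < 0.07
        # superuniformity: P(p <= t) <= t + sampling noise for every t
        for pv in (ph, pt, pc):
            tgrid = np.linspace(0.01, 0.99, 50)
            emp = np.mean(pv[:, None] <= tgrid[None, :], axis=0)
            assert np.all(emp <= tgrid + 4 * np.sqrt(tgrid * (1 - tgrid) / M) + 2 / B)

    def test_null_reuse_exactness(self, small_null, rng):
        grid, table, null = small_null
        z = rng.standard_normal(5)
        fresh = simulate_null(5, grid, B=2000, seed=42, table=table)
        a = ts.scan_and_test(z, np.eye(5), grid=grid, null=null, table=table)
        b = ts.scan_and_test(z, np.eye(5), grid=grid, null=fresh, table=table)
        assert a.p_hc == b.p_hc and a.p_tc == b.p_tc and a.p_combined == b.p_combined
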