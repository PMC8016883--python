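import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from logoscan import scan_engine as se
from logoscan.gwas_io import RegionRecord
from logoscan.scan_engine import (
    DataError,
    NullQmax,
    ScanConfig,
    bh_fdr,
    enumerate_windows,
    max_scan,
    merge_regions,
    peel_off_scan,
    qmax_batch,
    scan_statistic,
)


class TestScanStatistic:
    def test_hand_value(self):
        q = scan_statistic([1, 2], [1, 2], [1, 1], [0, 1], theta=0.5)
        assert q == pytest.approx(5 / np.sqrt(2))
        assert q == pytest.approx(3.5355339, abs=1e-6)

    def test_theta_zero_raw_inner_product(self):
        assert scan_statistic([1, 2], [1, 2], [1, 1], [0, 1], theta=0.0) == pytest.approx(5.0)

    def test_zero_z2(self):
        assert scan_statistic([1, 2], [0, 0], [1, 1], [0, 1], theta=0.5) == 0.0

    def test_bad_ld_score(self):
        with pytest.raises(DataError):
            scan_statistic([1.0], [1.0], [0.0], [0], theta=0.5)

    def test_empty_region(self):
        with pytest.raises(DataError):
            scan_statistic([1.0], [1.0], [1.0], [], theta=0.5)


class TestEnumerateWindows:
    def test_block_25_cap_30(self):
        # lengths {10, 20}: 16 + 6 = 22 windows (combinatorial oracle)
        wins = enumerate_windows(25, step=10, cap=30)
        assert len(wins) == 22
        lengths = {e - s for s, e in wins}
        assert lengths == {10, 20}
        # oracle: direct enumeration count
        assert len(wins) == sum(25 - L + 1 for L in (10, 20))

    def test_small_block_single_window(self):
        assert enumerate_windows(7, step=10) == [(0, 7)]

    def test_cap_binding(self):
        wins = enumerate_windows(50, step=10, cap=10)
        assert all(e - s == 10 for s, e in wins)
        assert len(wins) == 41


def brute_force_max(z1, z2, l, theta, windows):
    """Independent oracle: evaluate Q per window via the scalar definition."""
    best = None
    for (s, e) in windows:
        q = scan_statistic(z1, z2, l, list(range(s, e)), theta)
        key = (-abs(q), s, e - s)
        if best is None or key < best[0]:
            best = (key, q, (s, e))
    return best[1], best[2]


class TestMaxScan:
    def test_single_window(self):
        z = np.arange(5.0)
        q, w = max_scan(z, z, np.ones(5), 0.5, [(0, 5)])
        assert w == (0, 5)

    def test_planted_signal(self):
        rng = np.random.default_rng(0)
        z1 = rng.standard_normal(100) * 0.1
        z2 = rng.standard_normal(100) * 0.1
        z1[10:20] = z2[10:20] = 5.0
        wins = enumerate_windows(100, step=10, cap=30)
        q, w = max_scan(z1, z2, np.ones(100), 0.5, wins)
        assert w == (10, 20)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = int(rng.integers(12, 60))
            z1 = rng.standard_normal(m)
            z2 = rng.standard_normal(m)
            l = rng.uniform(1.0, 4.0, m)
            theta = rng.choice([0.4, 0.5, 0.7])
            wins = enumerate_windows(m, step=10, cap=int(rng.choice([10, 20, 30])))
            got_q, got_w = max_scan(z1, z2, l, theta, wins)
            exp_q, exp_w = brute_force_max(z1, z2, l, theta, wins)
            assert got_w == exp_w
            assert got_q == pytest.approx(exp_q)

    def test_no_windows(self):
        with pytest.raises(DataError):
            max_scan([1.0], [1.0], [1.0], 0.5, [])


class TestQmaxBatch:
    def test_matches_max_scan(self):
        rng = np.random.default_rng(7)
        m = 40
        prods = rng.standard_normal((5, m))
        l = rng.uniform(1, 3, m)
        out = qmax_batch(prods, l, 0.5, step=10, cap=20)
        wins = enumerate_windows(m, step=10, cap=20)
        for b in range(5):
            z1 = prods[b]
            q, _ = max_scan(z1, np.ones(m), l, 0.5, wins)
            assert out[b] == pytest.approx(abs(q))

    def test_homogeneity_in_scale(self):
        # scaling both z vectors by c scales Qmax (and q95) by c^2
        rng = np.random.default_rng(8)
        prods = rng.standard_normal((50, 30))
        l = np.ones(30)
        base = qmax_batch(prods, l, 0.6, step=10, cap=30)
        scaled = qmax_batch(4.0 * prods, l, 0.6, step=10, cap=30)  # c = 2
        np.testing.assert_allclose(scaled, 4.0 * base, rtol=1e-12)


class TestPeelOff:
    def null_from(self, draws):
        draws = np.asarray(draws, dtype=float)
        return NullQmax(draws=draws, q95=float(np.quantile(draws, 0.95)))

    def test_pure_null_usually_empty(self):
        rng = np.random.default_rng(3)
        m = 60
        cfg = ScanConfig(n_mc=200)
        null_prods = rng.standard_normal((400, m))
        l = np.ones(m)
        null = se.null_qmax_from_products(null_prods, l, 0.5, cfg, 30)
        hits = 0
        for _ in range(40):
            z1 = rng.standard_normal(m)
            z2 = rng.standard_normal(m)
            if peel_off_scan(z1, z2, l, null, 0.5, cfg, cap=30):
                hits += 1
        assert hits <= 8  # ~5% expected; allow binomial slack

    def test_two_planted_signals_recovered_disjoint(self):
        rng = np.random.default_rng(5)
        m = 100
        z1 = rng.standard_normal(m) * 0.1
        z2 = rng.standard_normal(m) * 0.1
        z1[10:20] = z2[10:20] = 4.0
        z1[60:70] = 4.0
        z2[60:70] = -4.0
        cfg = ScanConfig(n_mc=200)
        null = self.null_from(np.abs(np.random.default_rng(0).standard_normal(500)) * 3)
        found = peel_off_scan(z1, z2, np.ones(m), null, 0.5, cfg, cap=20)
        spans = sorted((f["start"], f["end"]) for f in found)
        assert len(found) >= 2
        covered = set()
        for s, e in spans:
            assert not (set(range(s, e)) & covered)  # pairwise disjoint
            covered |= set(range(s, e))
        assert any(s <= 10 and e >= 20 for s, e in spans)
        assert any(s <= 60 and e >= 70 for s, e in spans)
        signs = sorted(np.sign(f["q"]) for f in found)
        assert signs[0] == -1 and signs[-1] == 1

    def test_antisymmetry_under_z2_negation(self):
        rng = np.random.default_rng(9)
        m = 80
        z1 = rng.standard_normal(m)
        z2 = rng.standard_normal(m)
        z1[30:40] = z2[30:40] = 3.0
        null = self.null_from(np.abs(rng.standard_normal(300)) * 2)
        cfg = ScanConfig(n_mc=300)
        a = peel_off_scan(z1, z2, np.ones(m), null, 0.5, cfg, cap=20)
        b = peel_off_scan(z1, -z2, np.ones(m), null, 0.5, cfg, cap=20)
        assert len(a) == len(b) and len(a) >= 1
        for ra, rb in zip(a, b):
            assert (ra["start"], ra["end"]) == (rb["start"], rb["end"])
            assert rb["q"] == pytest.approx(-ra["q"])
            assert rb["p"] == ra["p"]


class TestMergeRegions:
    def rec(self, start, end, p=0.01, q=1.0, chrom="1"):
        return RegionRecord(chrom, start, end, 0, max(1, (end - start) // 1000), q, p, p)

    def test_gap_45kb_merged(self):
        merged = merge_regions([self.rec(1000, 5000, p=0.02), self.rec(50_000, 60_000, p=0.01)])
        assert len(merged) == 1
        assert (merged[0].start_bp, merged[0].end_bp) == (1000, 60_000)
        assert merged[0].p == 0.01

    def test_gap_150kb_unchanged(self):
        merged = merge_regions([self.rec(1000, 5000), self.rec(155_000, 160_000)])
        assert len(merged) == 2

    def test_idempotent(self):
        regions = [self.rec(0, 1000), self.rec(50_000, 51_000), self.rec(400_000, 401_000)]
        once = merge_regions(regions)
        twice = merge_regions(once)
        assert [(r.start_bp, r.end_bp) for r in once] == [(r.start_bp, r.end_bp) for r in twice]

    def test_different_chromosomes_never_merge(self):
        merged = merge_regions([self.rec(0, 1000, chrom="1"), self.rec(2000, 3000, chrom="2")])
        assert len(merged) == 2

    def test_output_gaps_exceed_threshold(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.integers(0, 2_000_000, 20))
        regions = [self.rec(int(s), int(s) + 500) for s in starts]
        merged = merge_regions(regions, gap_bp=100_000)
        for a, b in zip(merged, merged[1:]):
            assert b.start_bp - a.end_bp > 100_000


class TestBhFdr:
    def test_hand_case(self):
        q, reject = bh_fdr([0.001, 0.01, 0.04, 0.5], q=0.05)
        assert list(reject) == [True, True, False, False]

    def test_all_ones(self):
        _, reject = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_against_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, n)
            qv, rej = bh_fdr(p, q=0.05)
            rej_sm, qv_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(rej, rej_sm)
            np.testing.assert_allclose(qv, qv_sm, rtol=1e-10)

    def test_empty(self):
        qv, rej = bh_fdr([])
        assert len(qv) == 0 and len(rej) == 0


@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_bh_qvalues_bounded_and_monotone(p):
    qv, rej = bh_fdr(p, q=0.05)
    assert np.all(qv >= np.asarray(p) - 1e-15)
    assert np.all(qv <= 1.0)
    # rejection set is a lower set of p-values
    if rej.any():
        assert max(np.asarray(p)[rej]) <= min(
            np.asarray(p)[~rej], default=np.inf
        ) + 1e-15 or not (~rej).any()


class TestConfig:
    def test_theta_grid_validated(self):
        with pytest.raises(Exception):
            ScanConfig(theta_grid=(0.5, 1.5))

    def test_max_window_validated(self):
        with pytest.raises(Exception):
            ScanConfig(max_window=5, window_step=10)


class TestSelectTheta:
    def test_midpoint_convention_when_no_regions(self, small_panel):
        # zero z-scores can never beat a positive null quantile -> no regions
        # at any theta -> theta_hat falls back to the grid midpoint (0.55)
        from logoscan.gwas_io import HarmonizedPair

        m = small_panel.m
        df = small_panel.meta.copy()
        df["z1"] = 0.0
        df["z2"] = 0.0
        hp = HarmonizedPair(df=df, n1=500.0, n2=500.0)
        blocks_data = se._split_blocks(np.zeros(m, dtype=np.int64), hp.chrom)
        null_prods = np.random.default_rng(0).standard_normal((100, m))
        cfg = ScanConfig(n_mc=100)
        res = se.select_theta(
            hp, small_panel, np.ones(m), blocks_data, null_prods, cfg, 500, 500, cap=30
        )
        assert res.theta_hat == 0.55
        assert np.all(res.pis == 0.0)
        assert all(len(r) == 0 for r in res.regions_per_theta)
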