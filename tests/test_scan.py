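import itertools
import math

import numpy as np
import pytest
from shapely.geometry import box

from scanedge import Dataset, enumerate_zones, poisson_llr, scan

from conftest import build_region


def collinear_region(pops):
    pts = [(0.5 + i, 0.5) for i in range(len(pops))]
    return build_region(pts, pops, box(0, 0, len(pops), 1))


def grid_region(rows, cols, pops=None):
    pts = [(c + 0.5, r + 0.5) for r in range(rows) for c in range(cols)]
    if pops is None:
        pops = np.ones(rows * cols)
    return build_region(pts, pops, box(0, 0, cols, rows))


class TestEnumerateZones:
    def test_population_cap_blocks_growth(self):
        region = collinear_region([30, 30, 40])
        zones = enumerate_zones(region, 0.5)  # cap = 50
        from_first = [z for z in zones if z.center_id == "u0"]
        assert [set(z.member_ids) for z in from_first] == [{"u0"}]

    def test_fraction_one_gives_nested_zones_from_each_center(self):
        region = collinear_region([30, 30, 40])
        zones = enumerate_zones(region, 1.0)
        from_first = [set(z.member_ids) for z in zones if z.center_id == "u0"]
        assert from_first == [{"u0"}, {"u0", "u1"}, {"u0", "u1", "u2"}]

    def test_2x2_grid_half_cap_zones_match_brute_force(self):
        region = grid_region(2, 2)
        zones = enumerate_zones(region, 0.5)
        assert all(len(z) <= 2 for z in zones)
        # independent oracle: every (center, radius) member set with pop <= cap
        xy = region.centroids
        expected = set()
        for c in range(4):
            d = np.hypot(*(xy - xy[c]).T)
            for r in np.unique(d):
                members = frozenset(np.flatnonzero(d <= r))
                if len(members) <= 2:
                    expected.add(members)
        got = {
            frozenset(region.index_of(m) for m in z.member_ids) for z in zones
        }
        assert got == expected

    def test_distance_ties_included_together(self):
        # u1 and u2 are both exactly 1 away from u0: one zone covers both
        region = build_region(
            [(2, 2), (1, 2), (3, 2)], [1, 1, 1], box(0, 0, 4, 4)
        )
        zones = enumerate_zones(region, 1.0)
        from_center = [set(z.member_ids) for z in zones if z.center_id == "u0"]
        assert from_center == [{"u0"}, {"u0", "u1", "u2"}]

    def test_duplicate_member_sets_are_deduplicated(self):
        region = collinear_region([1, 1, 1])
        zones = enumerate_zones(region, 1.0)
        sets = [frozenset(z.member_ids) for z in zones]
        assert len(sets) == len(set(sets))

    def test_zone_invariants(self):
        region = grid_region(3, 3, np.arange(1.0, 10.0))
        for z in enumerate_zones(region, 0.5):
            assert z.center_id in z.member_ids
            assert z.pop_in <= 0.5 * region.total_population
            members = [region.index_of(m) for m in z.member_ids]
            assert z.pop_in == pytest.approx(region.populations[members].sum())


class TestPoissonLLR:
    def test_indicator_false_gives_zero(self):
        assert poisson_llr(1, 1.0, 5, 9.0) == 0.0

    def test_direct_evaluation_of_formula(self):
        # independent evaluation: 5 ln 5 + 5 ln(5/9)
        expected = 5 * math.log(5) + 5 * math.log(5 / 9)
        assert poisson_llr(5, 1.0, 5, 9.0) == pytest.approx(expected)
        assert expected == pytest.approx(5.1083, abs=1e-4)

    def test_zero_out_count_uses_xlogx_limit(self):
        val = poisson_llr(3, 2.0, 0, 4.0)
        assert val == pytest.approx(3 * math.log(3 / 2))

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            poisson_llr(1, 0.0, 1, 1.0)
        with pytest.raises(ValueError):
            poisson_llr(1, 1.0, 1, -2.0)


def brute_force_mlc(dataset, max_pop_fraction=0.5):
    """Exhaustive oracle: best conditional LLR over every circular zone,
    via direct loops (the incidence is the dataset's own cases/population
    ratio, as in the default scan statistic)."""
    region = dataset.region
    xy = region.centroids
    n_tot = dataset.total_cases
    lam = n_tot / dataset.total_population if n_tot else np.finfo(float).tiny
    cap = max_pop_fraction * region.total_population
    best = (-1.0, None)
    best_sets = []
    for c in range(region.n):
        d = np.hypot(*(xy - xy[c]).T)
        for r in sorted(set(d)):
            members = np.flatnonzero(d <= r)
            pop_in = region.populations[members].sum()
            if pop_in > cap:
                continue
            n_in = int(dataset.observed[members].sum())
            e_in = lam * pop_in
            e_out = lam * (region.total_population - pop_in)
            if n_in <= e_in or e_out <= 0:
                llr = 0.0
            else:
                llr = n_in * math.log(n_in / e_in)
                if n_tot - n_in > 0:
                    llr += (n_tot - n_in) * math.log((n_tot - n_in) / e_out)
            if llr > best[0] + 1e-12:
                best = (llr, frozenset(members))
                best_sets = [frozenset(members)]
            elif abs(llr - best[0]) <= 1e-12:
                best_sets.append(frozenset(members))
    return best[0], best_sets


class TestScan:
    @pytest.fixture
    def region5(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0.5, 4.5, size=(5, 2))
        return build_region(pts, rng.uniform(20, 100, 5), box(0, 0, 5, 5))

    def test_p_value_is_rank_over_replicates_plus_one(self, region5):
        zones = enumerate_zones(region5, 0.5)
        # a gross cluster: all cases in one SU
        obs = np.zeros(5, dtype=int)
        obs[0] = 50
        ds = Dataset(region=region5, lambda_=0.01, observed=obs)
        res = scan(ds, zones, n_mc=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.significant

    def test_zero_cases_gives_p_one_and_zero_llr(self, region5):
        zones = enumerate_zones(region5, 0.5)
        ds = Dataset(region=region5, lambda_=0.01, observed=np.zeros(5, dtype=int))
        res = scan(ds, zones, n_mc=99, seed=0)
        assert res.llr == 0.0
        assert res.p_value == 1.0

    def test_p_value_support(self, region5):
        zones = enumerate_zones(region5, 0.5)
        ds = Dataset(
            region=region5, lambda_=0.02, observed=np.array([3, 1, 0, 2, 1])
        )
        res = scan(ds, zones, n_mc=199, seed=3)
        assert res.p_value in {k / 200 for k in range(1, 201)}

    def test_mlc_matches_brute_force_oracle_over_random_datasets(self):
        rng = np.random.default_rng(2026)
        for trial in range(40):
            n = int(rng.integers(3, 7))
            pts = rng.uniform(0, 10, size=(n, 2))
            pops = rng.uniform(5, 80, n)
            region = build_region(pts, pops, box(-1, -1, 11, 11))
            lam = rng.uniform(0.005, 0.05)
            obs = rng.poisson(lam * pops * rng.uniform(0.5, 3))
            ds = Dataset(region=region, lambda_=lam, observed=obs)
            zones = enumerate_zones(region, 0.5)
            res = scan(ds, zones, n_mc=9, seed=trial)
            oracle_llr, oracle_sets = brute_force_mlc(ds)
            assert res.llr == pytest.approx(oracle_llr, abs=1e-9)
            got = frozenset(region.index_of(m) for m in res.mlc.member_ids)
            assert got in oracle_sets

    def test_mlc_llr_dominates_every_enumerated_zone(self, region5):
        zones = enumerate_zones(region5, 0.5)
        ds = Dataset(
            region=region5, lambda_=0.02, observed=np.array([5, 2, 0, 1, 4])
        )
        res = scan(ds, zones, n_mc=9, seed=1, lambda_mode="nominal")
        lam = ds.lambda_
        for z in zones:
            members = [region5.index_of(m) for m in z.member_ids]
            n_in = int(ds.observed[members].sum())
            llr = poisson_llr(
                n_in,
                lam * z.pop_in,
                ds.total_cases - n_in,
                lam * (ds.total_population - z.pop_in),
            )
            assert res.llr >= llr - 1e-12

    def test_poisson_replicates_option(self, region5):
        zones = enumerate_zones(region5, 0.5)
        ds = Dataset(
            region=region5, lambda_=0.02, observed=np.array([3, 1, 0, 2, 1])
        )
        res = scan(ds, zones, n_mc=99, seed=5, replicates="poisson")
        assert 0 < res.p_value <= 1

    def test_region_mismatch_rejected(self, region5):
        zones = enumerate_zones(region5, 0.5)
        other = grid_region(2, 2)
        ds = Dataset(region=other, lambda_=0.02, observed=np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="different regions"):
            scan(ds, zones, n_mc=9, seed=0)


def test_null_rejection_rate_and_p_uniformity():
    """Under risk homogeneity the scan rejects ~5% of datasets and its MC
    p-values are close to uniform on their discrete support."""
    from scanedge import simulate_null

    region = grid_region(5, 5, np.full(25, 40.0))
    zones = enumerate_zones(region, 0.5)
    pvals = []
    for k, ds in enumerate(simulate_null(region, 0.02, 400, seed=9)):
        res = scan(ds, zones, n_mc=99, seed=np.random.SeedSequence(entropy=9, spawn_key=(1, k)))
        pvals.append(res.p_value)
    pvals = np.array(pvals)
    rate = np.mean(pvals <= 0.05)
    # 95% binomial envelope around 0.05 at 400 datasets
    assert 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / 400) <= rate
    assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / 400)
    # validity: P(p <= g) never exceeds g beyond Monte-Carlo slack (ties in the
    # discrete counts make the rank p-value conservative, never liberal), and
    # the rejection-relevant lower tail is close to uniform
    grid = np.linspace(0.1, 0.9, 9)
    emp = np.array([(pvals <= g).mean() for g in grid])
    slack = 1.63 / np.sqrt(400)
    assert np.all(emp <= grid + slack)
    low = np.array([0.1, 0.2])
    emp_low = np.array([(pvals <= g).mean() for g in low])
    assert np.max(np.abs(emp_low - low)) < slack
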