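"""Great-circle geometry, thinning, join counts and Moran's I."""

import numpy as np
import pandas as pd
import pytest

from reefrestore import spatial_stats as sp


# ---------------------------------------------------------------------------
# haversine distance
# ---------------------------------------------------------------------------

class TestHaversine:
    def test_identity(self):
        assert sp.haversine_km(0.0, 0.0, 0.0, 0.0) == 0.0

    def test_quarter_circumference_to_pole(self):
        # equator to pole = 2*pi*R/4 = 10,007.5 km
        assert sp.haversine_km(0.0, 0.0, 0.0, 90.0) == pytest.approx(
            2 * np.pi * 6371.0 / 4.0, abs=0.1)

    def test_symmetry_random_pairs(self):
        rng = np.random.default_rng(0)
        lon = rng.uniform(-180, 179.9, (1000, 2))
        lat = rng.uniform(-90, 90, (1000, 2))
        d_ab = sp.haversine_km(lon[:, 0], lat[:, 0], lon[:, 1], lat[:, 1])
        d_ba = sp.haversine_km(lon[:, 1], lat[:, 1], lon[:, 0], lat[:, 0])
        np.testing.assert_allclose(d_ab, d_ba, rtol=0, atol=1e-9)

    def test_agrees_with_law_of_cosines(self):
        # independent spherical-law-of-cosines implementation
        rng = np.random.default_rng(1)
        lon = np.radians(rng.uniform(-180, 179.9, (500, 2)))
        lat = np.radians(rng.uniform(-89, 89, (500, 2)))
        cosang = (np.sin(lat[:, 0]) * np.sin(lat[:, 1])
                  + np.cos(lat[:, 0]) * np.cos(lat[:, 1])
                  * np.cos(lon[:, 1] - lon[:, 0]))
        d_loc = 6371.0 * np.arccos(np.clip(cosang, -1, 1))
        d_hav = sp.haversine_km(np.degrees(lon[:, 0]), np.degrees(lat[:, 0]),
                                np.degrees(lon[:, 1]), np.degrees(lat[:, 1]))
        assert np.max(np.abs(d_loc - d_hav)) < 0.5

    @pytest.mark.parametrize("lon,lat", [(200.0, 0.0), (0.0, 95.0), (-181.0, 10.0)])
    def test_rejects_out_of_range(self, lon, lat):
        with pytest.raises(ValueError):
            sp.haversine_km(lon, lat, 0.0, 0.0)


# ---------------------------------------------------------------------------
# distance thinning
# ---------------------------------------------------------------------------

class TestThinning:
    def test_single_locality(self):
        df = pd.DataFrame({"id": [7], "lon": [10.0], "lat": [5.0]})
        sub = sp.thin_by_distance(df, 150.0, seed=0)
        assert list(sub.ids) == [7]
        assert sub.min_pairwise_km == np.inf

    def test_two_close_points_forced_exclusion(self):
        # ~100 km apart at the equator (0.9 degrees of longitude)
        df = pd.DataFrame({"id": [0, 1], "lon": [0.0, 0.9], "lat": [0.0, 0.0]})
        sub = sp.thin_by_distance(df, 150.0, seed=0)
        assert len(sub) == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sp.thin_by_distance(pd.DataFrame(columns=["id", "lon", "lat"]), 150.0)

    def test_greedy_rule_matches_brute_force_replay(self):
        # 20-point clustered layout; the iteration order is the seeded
        # permutation, so replay the greedy rule independently.
        rng = np.random.default_rng(3)
        centers = [(0.0, 0.0), (20.0, 5.0), (-30.0, -10.0), (100.0, 15.0)]
        pts = []
        for cx, cy in centers:
            for _ in range(5):
                pts.append((cx + rng.normal(0, 0.8), cy + rng.normal(0, 0.8)))
        df = pd.DataFrame({"id": np.arange(20),
                           "lon": [p[0] for p in pts],
                           "lat": [p[1] for p in pts]})
        seed = 9
        sub = sp.thin_by_distance(df, 150.0, seed=seed)

        order = np.random.default_rng(seed).permutation(len(df))
        kept = [order[0]]
        for i in order[1:]:
            d = [sp.haversine_km(df.lon[j], df.lat[j], df.lon[i], df.lat[i])
                 for j in kept]
            if min(d) > 150.0:
                kept.append(i)
        assert sorted(sub.ids) == sorted(df.id[kept])

    def test_min_pairwise_exceeds_threshold(self, scattered_points):
        sub = sp.thin_by_distance(scattered_points, 300.0, seed=1)
        assert sub.min_pairwise_km > 300.0

    def test_idempotence(self, scattered_points):
        sub = sp.thin_by_distance(scattered_points, 300.0, seed=2)
        again = sp.thin_by_distance(
            scattered_points[scattered_points.id.isin(sub.ids)], 300.0, seed=99)
        assert sorted(again.ids) == sorted(sub.ids)


# ---------------------------------------------------------------------------
# join counts
# ---------------------------------------------------------------------------

def rook_lattice(n_side):
    n = n_side * n_side
    adj = np.zeros((n, n))
    for r in range(n_side):
        for c in range(n_side):
            i = r * n_side + c
            if c + 1 < n_side:
                adj[i, i + 1] = adj[i + 1, i] = 1
            if r + 1 < n_side:
                adj[i, i + n_side] = adj[i + n_side, i] = 1
    return adj


class TestJoinCounts:
    def test_checkerboard_perfect_dispersion(self):
        adj = rook_lattice(4)
        labels = np.array([(r + c) % 2 for r in range(4) for c in range(4)])
        res = sp.join_count_test(labels, adj)
        same = res.stats[res.stats.class_a == res.stats.class_b]
        assert (same.observed == 0).all()
        assert (same.z < -3).all()

    def test_homogeneous_blocks_clustering(self):
        adj = rook_lattice(4)
        labels = np.array([0] * 8 + [1] * 8)  # two row-blocks
        res = sp.join_count_test(labels, adj)
        same = res.stats[res.stats.class_a == res.stats.class_b]
        assert (same.z > 2).all()

    def test_single_class_degenerate_not_crash(self):
        adj = rook_lattice(3)
        res = sp.join_count_test(np.zeros(9, dtype=int), adj)
        assert res.degenerate
        assert np.isnan(res.same_class_p())

    def test_analytic_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        adj = rook_lattice(7)
        labels = rng.integers(0, 2, 49)
        res = sp.join_count_test(labels, adj, n_permutations=10000, seed=4)
        same = res.stats[res.stats.class_a == res.stats.class_b]
        for _, row in same.iterrows():
            # MC error with 10k permutations is ~0.005; the rest of the
            # slack covers the normal approximation of a discrete count
            assert abs(row.p - row.p_perm) < 0.08

    def test_permutation_mean_matches_expectation(self):
        rng = np.random.default_rng(2)
        adj = rook_lattice(5)
        labels = rng.integers(0, 2, 25)
        res = sp.join_count_test(labels, adj)
        iu, ju = np.where(np.triu(adj > 0, k=1))
        sims = []
        for _ in range(4000):
            perm = rng.permutation(labels)
            sims.append(np.sum((perm[iu] == 0) & (perm[ju] == 0)))
        exp = res.stats.loc[res.stats.class_a == 0, "expected"].iloc[0]
        assert np.mean(sims) == pytest.approx(exp, abs=3 * np.std(sims) / np.sqrt(4000))

    def test_total_joins_partition(self):
        rng = np.random.default_rng(7)
        adj = rook_lattice(5)
        labels = rng.integers(0, 2, 25)
        res = sp.join_count_test(labels, adj)
        assert res.stats.observed.sum() == res.n_edges


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

class TestMoransI:
    def test_smooth_gradient_positive_autocorrelation(self):
        rng = np.random.default_rng(0)
        lon = rng.uniform(-40, 40, 40)
        lat = rng.uniform(-20, 20, 40)
        w = sp.inverse_distance_weights(lon, lat)
        values = lon + 0.5 * lat  # smooth spatial gradient
        res = sp.morans_i(values, w)
        assert res.I > 0
        assert res.p < 0.05

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(21)
        lon = rng.uniform(-40, 40, 30)
        lat = rng.uniform(-20, 20, 30)
        w = sp.inverse_distance_weights(lon, lat)
        rejections = sum(sp.morans_i(rng.standard_normal(30), w).p < 0.05
                         for _ in range(500))
        assert 0.03 <= rejections / 500 <= 0.07

    def test_permutation_agrees_with_analytic(self):
        rng = np.random.default_rng(3)
        lon = rng.uniform(-40, 40, 30)
        lat = rng.uniform(-20, 20, 30)
        w = sp.inverse_distance_weights(lon, lat)
        res = sp.morans_i(rng.standard_normal(30), w, n_permutations=20000, seed=1)
        assert abs(res.p - res.p_perm) < 0.02

    def test_bounds_sanity(self):
        rng = np.random.default_rng(4)
        lon = rng.uniform(-40, 40, 25)
        lat = rng.uniform(-20, 20, 25)
        w = sp.inverse_distance_weights(lon, lat)
        res = sp.morans_i(rng.standard_normal(25), w)
        assert abs(res.I) <= 1.5

    def test_constant_values_raise(self):
        w = np.ones((5, 5))
        with pytest.raises(ValueError):
            sp.morans_i(np.ones(5), w)


# ---------------------------------------------------------------------------
# independent-subset sampler
# ---------------------------------------------------------------------------

class TestIndependentSubsetSampler:
    def test_random_labels_accepted_near_first_try(self):
        # lattice spaced ~165 km: thinning at 100 km keeps every point and
        # the 200 km neighbour band links adjacent points, so the first
        # attempt decides and succeeds with probability just under
        # 1 - alpha (min of two correlated same-class p-values)
        lon, lat = np.meshgrid(np.arange(10) * 1.5, np.arange(8) * 1.5)
        df = pd.DataFrame({"id": np.arange(80),
                           "lon": lon.ravel(), "lat": lat.ravel()})
        rng = np.random.default_rng(0)
        first_try = 0
        n_seeds = 200
        for s in range(n_seeds):
            labels = rng.integers(0, 2, len(df)).astype(bool)
            try:
                sub = sp.sample_independent_subset(
                    df, labels, threshold_km=100.0,
                    test="join_count", alpha=0.05, max_tries=3, seed=s)
                first_try += sub.n_attempts == 1
            except RuntimeError:
                pass  # a by-chance clustered labelling; expected at ~alpha rate
        assert 0.85 <= first_try / n_seeds <= 0.99

    def test_clustered_labels_reject_then_accept(self):
        # two adjacent dense patches with labels split by patch
        rng = np.random.default_rng(8)
        lon = np.concatenate([rng.uniform(-8, 0, 40), rng.uniform(0, 8, 40)])
        lat = rng.uniform(-8, 8, 80)
        df = pd.DataFrame({"id": np.arange(80), "lon": lon, "lat": lat})
        labels = np.array([True] * 40 + [False] * 40)
        attempts_small = []
        for s in range(10):
            try:
                sub = sp.sample_independent_subset(
                    df, labels, threshold_km=100.0, test="join_count",
                    alpha=0.05, max_tries=30, seed=s)
                attempts_small.append(sub.n_attempts)
            except RuntimeError:
                attempts_small.append(31)
        # clustered labels at a sub-cluster threshold need many tries
        assert np.mean(attempts_small) > 1.5
        # with a threshold far beyond the cluster scale the subsets shrink
        # below the clustering grain and get accepted
        accepted = 0
        for s in range(10):
            try:
                sp.sample_independent_subset(df, labels, threshold_km=800.0,
                                             test="join_count", alpha=0.05,
                                             max_tries=50, seed=s)
                accepted += 1
            except RuntimeError:
                pass
        assert accepted >= 8

    def test_max_tries_zero_fails_immediately(self, scattered_points):
        labels = np.zeros(len(scattered_points), dtype=bool)
        labels[::2] = True
        with pytest.raises(RuntimeError, match="0 tries"):
            sp.sample_independent_subset(scattered_points, labels, 100.0,
                                         max_tries=0, seed=0)

    def test_unknown_test_rejected(self, scattered_points):
        with pytest.raises(ValueError):
            sp.sample_independent_subset(scattered_points,
                                         np.zeros(len(scattered_points)), 100.0,
                                         test="geary")
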