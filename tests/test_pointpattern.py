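"""Point-pattern statistics against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonebed.pointpattern import (
    KFunctionResult,
    PointPattern2D,
    Window,
    centered_l,
    dbscan,
    density_map,
    fit_intensity,
    hopkins_skellam,
    k_function,
    quadrat_csr_test,
    select_eps,
    simulate_csr,
)

W10 = Window(0, 10, 0, 10)


def brute_force_dbscan(pts, eps, min_pts):
    """Independent density-reachability oracle: adjacency by pairwise
    distance, clusters = connected components of core points (ordered by
    smallest member index), border points claimed by the earliest-created
    adjacent cluster."""
    n = len(pts)
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    adj = d <= eps
    core = adj.sum(1) >= min_pts  # self included on the diagonal
    labels = np.zeros(n, dtype=int)
    comp = 0
    for i in range(n):
        if core[i] and labels[i] == 0:
            comp += 1
            # flood the core component
            frontier = {i}
            members = set()
            while frontier:
                j = frontier.pop()
                if j in members:
                    continue
                members.add(j)
                frontier |= {k for k in range(n) if core[k] and adj[j, k]} - members
            for j in members:
                labels[j] = comp
            # claim border points
            for j in range(n):
                if not core[j] and labels[j] == 0 and any(adj[j, k] for k in members):
                    labels[j] = comp
    return labels


class TestDensityMap:
    def test_single_point_peaks_at_point_and_integrates_to_one(self):
        pat = PointPattern2D([[5.0, 5.0]], W10)
        dm = density_map(pat, bandwidth=0.5, grid=(101, 101))
        iy, ix = np.unravel_index(np.argmax(dm["intensity"]), dm["intensity"].shape)
        assert dm["x"][ix] == pytest.approx(5.0, abs=0.1)
        assert dm["y"][iy] == pytest.approx(5.0, abs=0.1)
        integral = dm["intensity"].mean() * W10.area
        assert integral == pytest.approx(1.0, rel=0.01)

    def test_integral_equals_point_count(self, rng):
        for _ in range(5):
            pat = simulate_csr(rng.integers(20, 200), W10, rng)
            dm = density_map(pat, grid=(80, 80))
            assert dm["intensity"].mean() * W10.area == pytest.approx(pat.n, rel=0.01)

    def test_two_tight_clusters_two_maxima(self, rng):
        a = rng.normal([2, 2], 0.1, (40, 2))
        b = rng.normal([8, 8], 0.1, (40, 2))
        pat = PointPattern2D(np.clip(np.vstack([a, b]), 0, 10), W10)
        dm = density_map(pat, bandwidth=0.4, grid=(60, 60))
        z = dm["intensity"]
        iy, ix = np.unravel_index(np.argmax(z), z.shape)
        assert math.hypot(dm["x"][ix] - 2, dm["y"][iy] - 2) < 1 or math.hypot(
            dm["x"][ix] - 8, dm["y"][iy] - 8
        ) < 1
        # mask the first peak; the second maximum sits at the other cluster
        gx, gy = np.meshgrid(dm["x"], dm["y"])
        far = (gx - dm["x"][ix]) ** 2 + (gy - dm["y"][iy]) ** 2 > 4
        jy, jx = np.unravel_index(np.argmax(np.where(far, z, -1)), z.shape)
        assert math.hypot(dm["x"][jx] - dm["x"][ix], dm["y"][jy] - dm["y"][iy]) > 5

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            density_map(PointPattern2D([[1, 1]], W10), bandwidth=0)


class TestQuadratTest:
    def test_even_counts_give_zero_chi2_p_one(self):
        pts = np.array([[2.5, 2.5], [7.5, 2.5], [2.5, 7.5], [7.5, 7.5]])
        q = quadrat_csr_test(PointPattern2D(pts, W10), 2, 2, nsim=99, seed=0)
        assert q.chi2 == 0.0 and q.p_value == 1.0

    def test_hand_computed_chi2(self, rng):
        # all 10 points in one of four quadrats: chi2 = 30 with nbar = 2.5
        pts = np.column_stack([rng.uniform(0, 4, 10), rng.uniform(0, 4, 10)])
        q = quadrat_csr_test(PointPattern2D(pts, W10), 2, 2, nsim=9, seed=1)
        assert q.chi2 == pytest.approx(30.0)
        assert q.pearson_residuals.max() == pytest.approx((10 - 2.5) / math.sqrt(2.5))

    def test_minimum_attainable_p(self, rng):
        # an extreme pattern never beaten by CSR: p = 1/(nsim+1)
        pts = rng.uniform(0, 0.1, (50, 2))
        q = quadrat_csr_test(PointPattern2D(pts, W10), 4, 4, nsim=199, seed=2)
        assert q.p_value == pytest.approx(1 / 200)

    def test_counts_sum_to_n(self, rng):
        pat = simulate_csr(123, W10, rng)
        q = quadrat_csr_test(pat, 5, 3, nsim=9, seed=3)
        assert q.counts.sum() == 123


class TestKFunction:
    def test_five_point_toy_matches_pair_count(self):
        pts = np.array([(1, 1), (1, 2), (2, 1), (8, 8), (9, 9)], float)
        pat = PointPattern2D(pts, W10)
        k = k_function(pat, np.array([1.5]), correction="none")
        # 8 ordered pairs within 1.5; |W| pairs / (n (n-1)) = 100*8/20
        assert k.k_hat[0] == pytest.approx(40.0)

    def test_no_pairs_below_minimum_distance(self):
        pts = np.array([(2, 2), (8, 8)], float)
        k = k_function(PointPattern2D(pts, W10), np.array([1.0]), correction="none")
        assert k.k_hat[0] == 0.0

    def test_matches_brute_force_on_random_patterns(self, rng):
        for _ in range(10):
            pat = simulate_csr(30, W10, rng)
            r_grid = np.array([0.5, 1.5, 3.0])
            k = k_function(pat, r_grid, correction="none").k_hat
            d = np.sqrt(((pat.points[:, None] - pat.points[None, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            for r, kv in zip(r_grid, k):
                pairs = int((d <= r).sum())
                assert kv == pytest.approx(100 * pairs / (30 * 29))

    def test_csr_unbiasedness_with_border_correction(self):
        r = np.linspace(0, 2, 11)
        ks = []
        for s in range(40):
            pat = simulate_csr(300, W10, np.random.default_rng(s))
            ks.append(k_function(pat, r, correction="border").k_hat)
        mean_k = np.mean(ks, axis=0)
        assert np.allclose(mean_k[1:], math.pi * r[1:] ** 2, rtol=0.1)

    def test_k_monotone_nondecreasing(self, rng):
        pat = simulate_csr(100, W10, rng)
        k = k_function(pat, np.linspace(0, 3, 31)).k_hat
        assert (np.diff(k[~np.isnan(k)]) >= -1e-12).all()

    def test_centered_l_identities(self):
        r = np.linspace(0.1, 3, 30)
        csr = KFunctionResult(r=r, k_hat=math.pi * r**2, correction="none", inhomogeneous=False)
        assert np.allclose(centered_l(csr), 0.0, atol=1e-12)
        one = KFunctionResult(
            r=np.array([1.0]), k_hat=np.array([4 * math.pi]), correction="none", inhomogeneous=False
        )
        assert centered_l(one)[0] == pytest.approx(1.0)

    def test_inhomogeneous_reduces_to_homogeneous_scale(self, rng):
        pat = simulate_csr(200, W10, rng)
        lam = np.full(200, 2.0)  # constant intensity n/|W|
        r = np.array([1.0, 2.0])
        ki = k_function(pat, r, lam=lam, correction="border").k_hat
        kh = k_function(pat, r, correction="border").k_hat
        # same estimator up to the n/(n-1) pair normalisation
        assert np.allclose(ki * 200 / 199, kh, rtol=1e-9)

    def test_bad_inputs_rejected(self, rng):
        pat = simulate_csr(5, W10, rng)
        with pytest.raises(ValueError):
            k_function(pat, np.array([]))
        with pytest.raises(ValueError):
            k_function(PointPattern2D([[1, 1]], W10), np.array([1.0]))


class TestHopkinsSkellam:
    def test_hand_computed_worked_example(self):
        events = np.array([(0.0, 0.0), (0.0, 0.1)])
        pat = PointPattern2D(events, W10)
        res = hopkins_skellam(
            pat, m=2, sample_events=events, sample_locations=np.array([(5.0, 5.0), (9.0, 9.0)])
        )
        assert res.A == pytest.approx(0.02 / 209.22, rel=1e-9)
        assert res.interpretation == "clustered"

    def test_csr_compatible_on_uniform(self, rng):
        pat = simulate_csr(500, W10, rng)
        res = hopkins_skellam(pat, m=50, seed=rng)
        assert 0.5 < res.A < 2.0

    def test_m_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            hopkins_skellam(simulate_csr(5, W10, rng), m=10)


class TestDbscan:
    def test_two_blobs_plus_noise(self):
        pts = np.array(
            [(0, 0), (0.1, 0), (0, 0.1), (5, 5), (5.1, 5), (5, 5.1), (9, 9)], float
        )
        res = dbscan(pts, eps=0.3, min_pts=3)
        assert res.n_clusters == 2
        assert (res.labels == 0).sum() == 1
        oracle = brute_force_dbscan(pts, 0.3, 3)
        assert (res.labels == oracle).all()

    def test_fewer_points_than_min_pts_all_noise(self):
        res = dbscan(np.array([[0, 0], [1, 1]]), eps=0.5, min_pts=3)
        assert res.n_clusters == 0 and (res.labels == 0).all()

    def test_single_dense_cluster(self, rng):
        pts = rng.normal(0, 0.05, (20, 2))
        res = dbscan(pts, eps=1.0, min_pts=5)
        assert res.n_clusters == 1 and (res.labels == 1).all()

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 50))
            pts = rng.uniform(0, 4, (n, 2))
            eps = float(rng.uniform(0.2, 1.0))
            min_pts = int(rng.integers(2, 6))
            ours = dbscan(pts, eps, min_pts).labels
            oracle = brute_force_dbscan(pts, eps, min_pts)
            assert (ours == oracle).all()


class TestSelectEps:
    def test_two_blobs_suggests_intermediate_scale(self, rng):
        a = rng.normal([1, 1], 0.05, (30, 2))
        b = rng.normal([8, 8], 0.05, (30, 2))
        eps = select_eps(np.vstack([a, b]), k=4)
        assert 0.02 < eps < 7.0

    def test_uniform_grid_returns_spacing(self):
        xs, ys = np.meshgrid(np.arange(8), np.arange(8))
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        eps = select_eps(pts, k=4)
        assert 0.9 <= eps <= 1.5  # k=4 neighbours of a grid point sit at spacing 1

    def test_degenerate_minimum_size(self, rng):
        pts = rng.uniform(0, 1, (5, 2))
        assert select_eps(pts, k=4) > 0
        with pytest.raises(ValueError):
            select_eps(pts, k=5)


@given(st.integers(0, 10_000))
@settings(max_examples=20, derandomize=True, deadline=None)
def test_quadrat_counts_partition_any_pattern(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 60))
    pat = simulate_csr(n, W10, rng)
    q = quadrat_csr_test(pat, 4, 4, nsim=1, seed=rng)
    assert q.counts.sum() == n
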