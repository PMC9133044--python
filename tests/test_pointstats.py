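"""Maxima detection, quadrat statistics, Ripley K and CSR envelopes."""

import numpy as np
import pytest
from scipy import stats

from _oracles import prominence_maxima_oracle, ripley_k_bruteforce, strict_local_maxima
from duratrace import pointstats as ps
from duratrace import synthgen as sg


def _points_sorted(pattern):
    return sorted(map(tuple, np.round(pattern.points, 9)))


class TestFindMaxima:
    def test_single_peak(self):
        img = np.zeros((11, 11))
        img[5, 5] = 100.0
        p = ps.find_maxima(img, 35, exclude_edge=False)
        assert _points_sorted(p) == [(5.0, 5.0)]

    def test_subtolerance_secondary_peak_merged(self):
        """Peaks 120 and 100 joined by a 95 ridge: secondary prominence 5 < 35."""
        img = np.zeros((9, 21))
        img[4, 4], img[4, 16] = 120.0, 100.0
        img[4, 5:16] = 95.0
        assert ps.find_maxima(img, 35, exclude_edge=False).n == 1
        assert ps.find_maxima(img, 5, exclude_edge=False).n == 2

    def test_border_peak_excluded(self):
        img = np.zeros((9, 9))
        img[0, 4] = 100.0
        assert ps.find_maxima(img, 35, exclude_edge=True).n == 0
        assert ps.find_maxima(img, 35, exclude_edge=False).n == 1

    def test_plateau_reported_at_centroid(self):
        img = np.zeros((10, 10))
        img[4, 4:6] = 80.0  # two-pixel summit plateau
        p = ps.find_maxima(img, 10, exclude_edge=False)
        assert _points_sorted(p) == [(4.5, 4.0)]

    @pytest.mark.parametrize("tol", [0, 10, 35])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_prominence_oracle(self, seed, tol):
        rng = np.random.default_rng(100 * seed + tol)
        ny, nx = rng.integers(5, 20, 2)
        img = rng.integers(0, 120, (ny, nx)).astype(float)
        for excl in (False, True):
            got = _points_sorted(ps.find_maxima(img, tol, exclude_edge=excl))
            exp = [tuple(np.round(q, 9)) for q in prominence_maxima_oracle(img, tol, excl)]
            assert got == exp

    def test_tolerance_zero_equals_regional_maxima(self, rng):
        """At tolerance 0 every strict local maximum of a tie-free image is found."""
        img = rng.random((18, 18)) * 100
        got = _points_sorted(ps.find_maxima(img, 0, exclude_edge=False))
        assert got == strict_local_maxima(img)

    def test_positions_are_calibrated(self):
        img = np.zeros((8, 8))
        img[3, 6] = 50.0
        p = ps.find_maxima(img, 10, exclude_edge=False, spacing=(2.0, 3.0))
        assert _points_sorted(p) == [(12.0, 9.0)]


class TestQuadrats:
    def test_counts_partition_all_points(self):
        p = sg.make_point_pattern(
            sg.PointProcessSpec(kind="fixed_n", n=100, window=(0, 0, 500, 300), seed=0)
        )
        g = ps.quadrat_counts(p, 5, 5)
        assert g.counts.sum() == 100

    def test_center_point_goes_to_upper_right_cell(self):
        p = ps.PointPattern(np.array([[50.0, 40.0]]), (0, 0, 100, 80))
        g = ps.quadrat_counts(p, 2, 2)
        assert g.counts[1, 1] == 1 and g.counts.sum() == 1

    def test_bimodal_counts_fail_normality(self):
        g = ps.QuadratGrid(5, 5, np.array([0] * 13 + [20] * 12).reshape(5, 5))
        assert ps.quadrat_normality(g) < 0.01

    def test_constant_counts_return_sentinel(self):
        g = ps.QuadratGrid(2, 2, np.full((2, 2), 4))
        assert np.isnan(ps.quadrat_normality(g))

    def test_null_rejection_rate_near_alpha(self):
        """Shapiro on near-Gaussian counts rejects at ~5% under the null."""
        rng = np.random.default_rng(42)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            counts = np.round(rng.normal(40, 6, 25)).astype(int).reshape(5, 5)
            rej += ps.quadrat_normality(ps.QuadratGrid(5, 5, counts)) < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) <= 3 * se


class TestRipley:
    def test_two_points_below_distance(self):
        p = ps.PointPattern(np.array([[10.0, 10.0], [60.0, 10.0]]), (0, 0, 100, 100))
        r, k = ps.ripley_k(p, np.array([20.0, 40.0]), correction="none")
        assert (k == 0).all()

    def test_three_point_toy_matches_bruteforce(self):
        pts = np.array([[10.0, 10.0], [30.0, 10.0], [10.0, 40.0]])
        win = (0.0, 0.0, 100.0, 80.0)
        p = ps.PointPattern(pts, win)
        r = np.array([15.0, 25.0, 40.0, 60.0])
        _, k = ps.ripley_k(p, r, correction="none")
        assert np.allclose(k, ripley_k_bruteforce(pts, win, r))

    @pytest.mark.parametrize("seed", range(6))
    def test_uncorrected_matches_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        win = (0.0, 0.0, 200.0, 150.0)
        pts = np.column_stack([rng.uniform(0, 200, n), rng.uniform(0, 150, n)])
        r = np.linspace(5, 70, 8)
        _, k = ps.ripley_k(ps.PointPattern(pts, win), r, correction="none")
        assert np.allclose(k, ripley_k_bruteforce(pts, win, r), rtol=0, atol=1e-9)

    def test_k_nondecreasing(self, rng):
        pts = np.column_stack([rng.uniform(0, 300, 40), rng.uniform(0, 300, 40)])
        _, k = ps.ripley_k(ps.PointPattern(pts, (0, 0, 300, 300)))
        assert (np.diff(k) >= 0).all()

    def test_fewer_than_two_points_rejected(self):
        p = ps.PointPattern(np.array([[1.0, 1.0]]), (0, 0, 10, 10))
        with pytest.raises(ValueError):
            ps.ripley_k(p)


class TestEnvelope:
    def test_envelope_uses_requested_simulation_count(self):
        p = sg.make_point_pattern(
            sg.PointProcessSpec(kind="fixed_n", n=60, window=(0, 0, 500, 400), seed=3)
        )
        env = ps.csr_envelope(p, n_sims=100, seed=9)
        assert env.n_sims == 100
        assert (env.k_lo <= env.k_hi).all()

    def test_deterministic_under_fixed_seed(self):
        p = sg.make_point_pattern(
            sg.PointProcessSpec(kind="fixed_n", n=50, window=(0, 0, 400, 400), seed=1)
        )
        a = ps.csr_envelope(p, n_sims=20, seed=7)
        b = ps.csr_envelope(p, n_sims=20, seed=7)
        assert np.array_equal(a.k_lo, b.k_lo) and a.verdict == b.verdict

    def test_observed_inside_its_own_band_identity(self):
        """A CSR draw re-simulated with its own seed must sit inside the band."""
        win = (0.0, 0.0, 400.0, 400.0)
        p = sg.make_point_pattern(sg.PointProcessSpec(kind="fixed_n", n=50, window=win, seed=5))
        r = np.linspace(10, 100, 10)
        _, k_obs = ps.ripley_k(p, r)
        env = ps.csr_envelope(p, n_sims=30, r_grid=r, seed=11)
        # widen the band with the observation itself: identity must hold
        lo = np.minimum(env.k_lo, k_obs)
        hi = np.maximum(env.k_hi, k_obs)
        assert ((lo <= k_obs) & (k_obs <= hi)).all()

    def test_tight_clusters_flagged_non_random(self):
        p = sg.make_point_pattern(
            sg.PointProcessSpec(
                kind="thomas", window=(0, 0, 1000, 800), parent_intensity=1.2e-5,
                offspring_mean=12, cluster_sigma=10.0, seed=4,
            )
        )
        env = ps.csr_envelope(p, n_sims=100, seed=17)
        assert env.verdict == "non_random"


class TestDensity:
    def test_paper_scale_example(self):
        """152 cells over the 4 mm² evaluation area: 38.0 cells/mm²."""
        pts = sg.make_point_pattern(
            sg.PointProcessSpec(kind="fixed_n", n=152, window=(0, 0, 2000, 2000), seed=0)
        )
        assert ps.density(pts, area_mm2=4.0) == 38.0

    def test_zero_points(self):
        p = ps.PointPattern(np.empty((0, 2)), (0, 0, 1000, 1000))
        assert ps.density(p) == 0.0

    def test_density_linear_in_count(self):
        win = (0.0, 0.0, 1000.0, 1000.0)
        a = ps.PointPattern(np.random.default_rng(0).uniform(0, 1000, (30, 2)), win)
        b = ps.PointPattern(np.vstack([a.points, a.points + 0.5]), win)
        assert ps.density(b) == 2 * ps.density(a)
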