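"""Centerline tracing, segmentation and morphometry."""

import numpy as np
import pytest

from _oracles import path_cost, shortest_path_oracle
from duratrace import enhance as en
from duratrace import trace as tr
from duratrace.enhance import EnhancedImage, ImageStack3D

SQ2 = np.sqrt(2.0)


def _enh_from_cost(cost):
    """Wrap an explicit cost image (P = 1 - cost) for the tracer."""
    return EnhancedImage(P=1.0 - np.asarray(cost, float), spacing=(1.0, 1.0))


class TestCenterline:
    def test_uniform_cost_straight_segment(self):
        c = np.full((20, 30), 0.2)
        cl = tr.trace_centerline(_enh_from_cost(c), tr.SeedPair((5, 3), (5, 23)), eps=1e-3)
        # chamfer geodesic on uniform cost: axis-aligned straight run
        assert cl.total_cost == pytest.approx((0.2 + 1e-3) * 20)
        assert (cl.points2d[:, 0] == 5).all()

    def test_degenerate_single_point(self):
        c = np.full((10, 10), 0.5)
        cl = tr.trace_centerline(_enh_from_cost(c), tr.SeedPair((4, 4), (4, 4)))
        assert len(cl.points2d) == 1 and cl.total_cost == 0.0

    def test_corridor_beats_wall(self, rng):
        cost = np.full((21, 21), 0.9)
        cost[10, :] = 0.01  # low-cost corridor
        cost[:10, 10] = 5.0  # wall above it
        enh = _enh_from_cost(np.clip(cost, 0, 1))
        cost = enh.cost
        cl = tr.trace_centerline(enh, tr.SeedPair((0, 0), (0, 20)), eps=1e-3)
        exp_cost, _ = shortest_path_oracle(cost, 1e-3, (0, 0), (0, 20))
        assert path_cost(cost, 1e-3, cl.points2d) == pytest.approx(exp_cost, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_random_costs(self, seed):
        rng = np.random.default_rng(seed)
        ny, nx = rng.integers(8, 25, 2)
        cost = rng.random((ny, nx))
        p0 = tuple(int(v) for v in (rng.integers(ny), rng.integers(nx)))
        p1 = tuple(int(v) for v in (rng.integers(ny), rng.integers(nx)))
        enh = _enh_from_cost(cost)
        cl = tr.trace_centerline(enh, tr.SeedPair(p0, p1), eps=1e-3)
        exp_cost, _ = shortest_path_oracle(enh.cost, 1e-3, p0, p1)
        assert path_cost(enh.cost, 1e-3, cl.points2d) == exp_cost

    def test_swapping_seeds_preserves_cost(self, rng):
        cost = rng.random((15, 15))
        enh = _enh_from_cost(cost)
        a = tr.trace_centerline(enh, tr.SeedPair((1, 2), (13, 11)))
        b = tr.trace_centerline(enh, tr.SeedPair((13, 11), (1, 2)))
        assert a.total_cost == pytest.approx(b.total_cost, rel=1e-12)

    def test_path_is_8_connected_and_ends_on_seeds(self, rng):
        cost = rng.random((12, 18))
        cl = tr.trace_centerline(_enh_from_cost(cost), tr.SeedPair((0, 0), (11, 17)))
        steps = np.abs(np.diff(cl.points2d, axis=0))
        assert steps.max() == 1
        assert tuple(cl.points2d[0]) == (0, 0) and tuple(cl.points2d[-1]) == (11, 17)

    def test_unreachable_seed_rejected(self):
        cost = np.full((9, 9), np.inf)
        cost[0, :2] = 0.1
        with pytest.raises(ValueError, match="not connected"):
            tr.trace_centerline(_enh_from_cost(cost), tr.SeedPair((0, 0), (8, 8)))


def _tube_setup(radius_px=4, length=60):
    P = np.zeros((31, length + 10))
    rows = np.arange(31)
    tube = np.abs(rows - 15) <= radius_px
    P[tube, 5: 5 + length] = 1.0
    cl = tr.Centerline(
        points2d=np.column_stack([np.full(length, 15), np.arange(5, 5 + length)]),
        total_cost=0.0,
    )
    return EnhancedImage(P=P, spacing=(1.0, 1.0)), cl, P.astype(bool)


class TestSegmentation:
    def test_tube_recovered_within_tolerance(self):
        enh, cl, tube = _tube_setup()
        mask = tr.segment_axon(enh, cl, iterations=50)
        assert mask[cl.points2d[:, 0], cl.points2d[:, 1]].all()
        from scipy import ndimage

        dil = ndimage.binary_dilation(tube, iterations=2)
        assert (mask <= dil).all()
        true_area = tube.sum()
        assert abs(mask.sum() - true_area) / true_area <= 0.2

    def test_zero_speed_returns_initialization(self):
        enh = EnhancedImage(P=np.zeros((20, 20)), spacing=(1.0, 1.0))
        cl = tr.Centerline(points2d=np.array([[10, 3], [10, 4], [10, 5]]), total_cost=0.0)
        with pytest.warns(UserWarning, match="zero propagation"):
            mask = tr.segment_axon(enh, cl)
        from scipy import ndimage

        init = np.zeros((20, 20), bool)
        init[10, 3:6] = True
        assert np.array_equal(mask, ndimage.binary_dilation(init))

    def test_more_smoothing_never_grows_perimeter(self):
        from skimage.measure import perimeter

        enh, cl, _ = _tube_setup()
        perims = [
            perimeter(tr.segment_axon(enh, cl, iterations=40, smoothing=s))
            for s in (1, 2, 4)
        ]
        assert perims[0] >= perims[1] >= perims[2]

    def test_mask_single_connected_component(self):
        enh, cl, _ = _tube_setup()
        from scipy import ndimage

        mask = tr.segment_axon(enh, cl, iterations=30)
        _, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 1


class TestMorphometry:
    def test_straight_centerline_length_in_um(self):
        """101 collinear pixels along x at 1.14 µm spacing measure 114.0 µm."""
        stack = ImageStack3D(np.ones((3, 9, 110)), spacing=(1.14, 1.14, 1.0))
        pts = np.column_stack([np.full(101, 4), np.arange(101)])
        cl = tr.Centerline(points2d=pts, total_cost=0.0)
        mask = np.ones((9, 110), bool)
        tr.measure_axon(mask, cl, stack, z_smooth_sigma=0)
        assert cl.length3d == pytest.approx(114.0, rel=1e-9)

    def test_diagonal_z_climb_length(self):
        """One z-step per x-step over 10 steps at unit spacing: 10*sqrt(2)."""
        v = np.zeros((11, 3, 11))
        for i in range(11):
            v[i, 1, i] = 100.0
        stack = ImageStack3D(v, spacing=(1.0, 1.0, 1.0))
        pts = np.column_stack([np.full(11, 1), np.arange(11)])
        cl = tr.Centerline(points2d=pts, total_cost=0.0)
        tr.measure_axon(np.ones((3, 11), bool), cl, stack, z_smooth_sigma=0)
        assert cl.length3d == pytest.approx(10 * SQ2, rel=1e-9)

    def test_tube_diameter_from_distance_transform(self):
        """Rasterized tube of radius 3 px: mean diameter within 1 px of 6 px."""
        mask = np.zeros((21, 40), bool)
        rows = np.arange(21)
        mask[np.abs(rows - 10) < 3, :] = True
        pts = np.column_stack([np.full(30, 10), np.arange(5, 35)])
        cl = tr.Centerline(points2d=pts, total_cost=0.0)
        d = tr.axon_diameters(mask, cl, (1.14, 1.14))
        assert abs(d.mean() - 6 * 1.14) <= 1.14

    def test_centerline_outside_mask_rejected(self):
        stack = ImageStack3D(np.ones((2, 5, 5)))
        cl = tr.Centerline(points2d=np.array([[2, 2]]), total_cost=0.0)
        with pytest.raises(ValueError, match="outside mask"):
            tr.measure_axon(np.zeros((5, 5), bool), cl, stack)

    def test_z_lift_follows_brightest_plane(self):
        v = np.zeros((6, 3, 20))
        v[4, 1, :] = 50.0  # axon lives at z-index 4
        stack = ImageStack3D(v, spacing=(1.0, 1.0, 1.0))
        pts = np.column_stack([np.full(20, 1), np.arange(20)])
        cl = tr.Centerline(points2d=pts, total_cost=0.0)
        tr.measure_axon(np.ones((3, 20), bool), cl, stack, z_smooth_sigma=0)
        assert (cl.points3d[:, 2] == 4.0).all()
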