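"""Waypoint segmentation, iterative cleaning, resampling, and profiles."""

import numpy as np
import pytest

import tractprof as tp
from tractprof.containers import ScalarMap

from conftest import make_bundle


def straight_fiber(z0=0.0, z1=60.0, x=30.0, y=30.0, n=40):
    z = np.linspace(z0, z1, n)
    return np.column_stack([np.full(n, x), np.full(n, y), z])


class TestSegmentation:
    roi1 = tp.WaypointROI("r1", box=([25, 25, 5], [35, 35, 10]), order=1)
    roi2 = tp.WaypointROI("r2", box=([25, 25, 50], [35, 35, 55]), order=2)

    def test_fiber_through_both_rois_kept(self):
        group = tp.segment_by_waypoints([straight_fiber()], self.roi1, self.roi2)
        assert len(group) == 1

    def test_fiber_through_one_roi_discarded(self):
        short = straight_fiber(z1=30.0)  # reaches ROI1 only
        with pytest.warns(UserWarning, match="no streamlines"):
            group = tp.segment_by_waypoints([short], self.roi1, self.roi2)
        assert len(group) == 0

    def test_reversed_fiber_reoriented(self):
        backwards = straight_fiber()[::-1]
        group = tp.segment_by_waypoints([backwards], self.roi1, self.roi2)
        assert len(group) == 1
        assert group.fibers[0][0, 2] < group.fibers[0][-1, 2]

    def test_mask_roi(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[28:33, 28:33, 5:10] = True
        roi1 = tp.WaypointROI("m1", mask=mask, affine=np.eye(4), order=1)
        mask2 = np.zeros((40, 40, 40), dtype=bool)
        mask2[28:33, 28:33, 30:36] = True
        roi2 = tp.WaypointROI("m2", mask=mask2, affine=np.eye(4), order=2)
        group = tp.segment_by_waypoints([straight_fiber()], roi1, roi2)
        assert len(group) == 1

    def test_roi_validation(self):
        with pytest.raises(ValueError):
            tp.WaypointROI("bad", box=([0, 0, 0], [0, 1, 1]))
        with pytest.raises(ValueError):
            tp.WaypointROI("bad", mask=np.zeros((2, 2, 2), bool), affine=np.eye(4))


class TestCleaning:
    def test_identical_fibers_unchanged(self):
        fibers = [straight_fiber() for _ in range(50)]
        group = tp.FiberGroup("same", fibers)
        assert len(tp.clean_fibers(group)) == 50

    def test_planted_outlier_is_unique_removal(self, bundle_with_outlier):
        cleaned = tp.clean_fibers(bundle_with_outlier)
        assert len(cleaned) == 49
        assert all(f[0, 0] < 60.0 for f in cleaned.fibers)

    def test_cleaning_is_idempotent(self, bundle_with_outlier):
        once = tp.clean_fibers(bundle_with_outlier)
        twice = tp.clean_fibers(once)
        assert len(twice) == len(once)

    def test_overlong_fiber_removed(self):
        group = make_bundle(n_inliers=40, spread=0.2, seed=2)
        group.fibers.append(straight_fiber(z0=-60.0, z1=60.0, n=80))
        cleaned = tp.clean_fibers(group)
        assert len(cleaned) == 40
        assert max(cleaned.lengths()) < 100

    def test_order_invariance(self, bundle_with_outlier):
        rng = np.random.default_rng(1)
        shuffled = tp.FiberGroup(
            "bundle", [bundle_with_outlier.fibers[i] for i in rng.permutation(50)]
        )
        a = sorted(tuple(f[0]) for f in tp.clean_fibers(bundle_with_outlier).fibers)
        b = sorted(tuple(f[0]) for f in tp.clean_fibers(shuffled).fibers)
        assert a == b

    def test_tiny_group_warns(self):
        group = tp.FiberGroup("tiny", [straight_fiber(), straight_fiber(x=31.0)])
        with pytest.warns(UserWarning, match="fewer than 3"):
            cleaned = tp.clean_fibers(group)
        assert len(cleaned) == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            tp.clean_fibers(tp.FiberGroup("empty", []))


class TestResample:
    def test_straight_segment_equal_spacing(self):
        out = tp.resample_fiber(np.array([[0.0, 0, 0], [0, 0, 50.0]]), 100)
        assert np.allclose(np.diff(out[:, 2]), 50.0 / 99)
        assert np.allclose(out[0], [0, 0, 0]) and np.allclose(out[-1], [0, 0, 50])

    def test_already_uniform_collinear_is_fixed_point(self):
        pts = np.column_stack([np.zeros(100), np.zeros(100), np.linspace(0, 30, 100)])
        out = tp.resample_fiber(pts, 100)
        assert np.abs(out - pts).max() < 1e-9

    def test_semicircle_arc_spacing(self):
        r = 25.0
        th = np.linspace(0, np.pi, 60)
        semi = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros_like(th)])
        out = tp.resample_fiber(semi, 100)
        seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.all(np.abs(seg - np.pi * r / 99) / (np.pi * r / 99) < 0.01)

    def test_degenerate_fiber_rejected(self):
        with pytest.raises(ValueError):
            tp.resample_fiber(np.array([[1.0, 1, 1]]))
        with pytest.raises(ValueError, match="degenerate"):
            tp.resample_fiber(np.array([[1.0, 1, 1], [1.0, 1, 1]]))


class TestProfile:
    affine = np.eye(4)

    def test_uniform_field_gives_constant_profile(self):
        fa = ScalarMap(np.full((70, 70, 70), 0.5), self.affine)
        group = make_bundle(n_inliers=20, seed=3)
        profile = tp.tract_profile(group, fa)
        assert np.allclose(profile.values, 0.5)

    def test_single_fiber_profile_is_interpolated_fa(self):
        data = np.tile(np.linspace(0.2, 0.8, 70)[None, None, :], (70, 70, 1))
        fa = ScalarMap(data, self.affine)
        fiber = straight_fiber(z0=5.0, z1=60.0)
        profile = tp.tract_profile(tp.FiberGroup("one", [fiber]), fa)
        z = np.linspace(5.0, 60.0, 100)
        expected = np.interp(z, np.arange(70), np.linspace(0.2, 0.8, 70))
        assert np.allclose(profile.values, expected, atol=1e-9)

    def test_symmetric_fibers_average_equally(self):
        """Two fibers symmetric about the core with FA a and b: (a+b)/2."""
        data = np.zeros((70, 70, 70))
        data[:, 28, :] = 0.3
        data[:, 32, :] = 0.7
        fa = ScalarMap(data, self.affine)
        f1 = straight_fiber(y=28.0)
        f2 = straight_fiber(y=32.0)
        profile = tp.tract_profile(tp.FiberGroup("pair", [f1, f2]), fa)
        assert np.allclose(profile.values, 0.5, atol=1e-9)

    def test_profile_within_sampled_range(self):
        rng = np.random.default_rng(4)
        fa = ScalarMap(rng.uniform(0.1, 0.9, (70, 70, 70)), self.affine)
        group = make_bundle(n_inliers=15, seed=5)
        profile = tp.tract_profile(group, fa)
        from tractprof.tracts import resample_fiber
        from scipy.ndimage import map_coordinates

        sampled = np.stack(
            [
                map_coordinates(fa.data, resample_fiber(f, 100).T, order=1, mode="nearest")
                for f in group.fibers
            ]
        )
        assert np.all(profile.values >= sampled.min(axis=0) - 1e-12)
        assert np.all(profile.values <= sampled.max(axis=0) + 1e-12)

    def test_empty_group_gives_none(self):
        fa = ScalarMap(np.full((5, 5, 5), 0.5), self.affine)
        assert tp.tract_profile(tp.FiberGroup("empty", []), fa) is None


def test_profiles_to_long():
    from tractprof.tracts import profiles_to_long

    p = tp.TractProfile(tract="Left Arcuate", values=np.linspace(0, 1, 100), subject="s1")
    table = profiles_to_long([p, None])
    assert len(table) == 100
    assert set(table.columns) == {"subject", "tract", "node", "fa"}
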