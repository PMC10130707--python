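import numpy as np
import pytest

from knotph.curve_io import PointCloud
from knotph.synthetic_curves import (add_noise, crossing_windows, depth_label,
                                     make_open_trefoil,
                                     make_unknotted_partner)


class TestMakeOpenTrefoil:
    def test_no_tails_core_spans_all_and_shallow(self):
        c = make_open_trefoil(n_core=40, tail_lengths=(0, 0), seed=0)
        assert c.knot_core == (0, 39)
        assert c.depth_category == "shallow"

    def test_sizes_and_spacing(self):
        c = make_open_trefoil(n_core=100, tail_lengths=(100, 100),
                              spacing=3.8, seed=1)
        assert len(c) == 300
        steps = np.linalg.norm(np.diff(c.points, axis=0), axis=1)
        assert abs(steps.mean() - 3.8) / 3.8 < 0.05

    def test_determinism(self):
        a = make_open_trefoil(n_core=40, tail_lengths=(8, 3), seed=42)
        b = make_open_trefoil(n_core=40, tail_lengths=(8, 3), seed=42)
        assert a.points.tobytes() == b.points.tobytes()

    def test_different_seeds_differ(self):
        a = make_open_trefoil(n_core=40, tail_lengths=(2, 2), seed=1)
        b = make_open_trefoil(n_core=40, tail_lengths=(2, 2), seed=2)
        assert not np.allclose(a.points, b.points)

    def test_depth_flips_with_tail_length(self):
        shallow = make_open_trefoil(n_core=40, tail_lengths=(2, 2), seed=0)
        deep = make_open_trefoil(n_core=40, tail_lengths=(20, 20), seed=0)
        assert shallow.depth_category == "shallow"
        assert deep.depth_category == "deep"

    def test_min_tail_fraction_increases_with_tails(self):
        fracs = []
        for t in (0, 4, 10, 20, 40):
            c = make_open_trefoil(n_core=40, tail_lengths=(t, t), seed=0)
            fracs.append(min(t, t) / len(c))
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_knot_core_interval(self):
        c = make_open_trefoil(n_core=40, tail_lengths=(7, 12), seed=0)
        assert c.knot_core == (7, 46)
        assert len(c) == 59

    def test_small_core_rejected(self):
        with pytest.raises(ValueError):
            make_open_trefoil(n_core=20, tail_lengths=(0, 0), seed=0)

    def test_tails_leave_core_bounding_box(self):
        c = make_open_trefoil(n_core=40, tail_lengths=(15, 15), seed=3)
        lo, hi = c.knot_core
        core = c.points[lo:hi + 1]
        bmin, bmax = core.min(axis=0), core.max(axis=0)
        for tail in (c.points[:lo], c.points[hi + 1:]):
            far_end = tail[0] if len(tail) and np.linalg.norm(
                tail[0] - core.mean(0)) > np.linalg.norm(
                tail[-1] - core.mean(0)) else tail[-1]
            assert np.any((far_end < bmin) | (far_end > bmax))


class TestDepthLabel:
    @pytest.mark.parametrize("min_tail,total,expected", [
        (0, 100, "shallow"),
        (5, 100, "shallow"),
        (25, 100, "deep"),
        (30, 100, "deep"),
        (10, 100, "neither"),
    ])
    def test_thresholds(self, min_tail, total, expected):
        assert depth_label(min_tail, total) == expected


class TestUnknottedPartner:
    @pytest.fixture
    def pair(self):
        curve = make_open_trefoil(n_core=60, tail_lengths=(6, 6), seed=4)
        window = crossing_windows(curve)[0]
        return curve, make_unknotted_partner(curve, window), window

    def test_locality(self, pair):
        curve, partner, (lo, hi) = pair
        outside = np.ones(len(curve), dtype=bool)
        outside[lo:hi + 1] = False
        assert curve.points[outside].tobytes() == \
            partner.points[outside].tobytes()

    def test_modified_count_equals_window_length(self, pair):
        curve, partner, (lo, hi) = pair
        moved = np.linalg.norm(partner.points - curve.points, axis=1) > 0
        assert moved.sum() == hi - lo + 1

    def test_displacement_bounded_by_pass_distance(self, pair):
        curve, partner, (lo, hi) = pair
        centre = (lo + hi) // 2
        d_xy = np.linalg.norm(
            curve.points[:, :2] - curve.points[centre, :2], axis=1)
        idx = np.arange(len(curve))
        d_xy[np.abs(idx - centre) <= (hi - lo + 2)] = np.inf
        other = int(np.argmin(d_xy))
        separation = np.linalg.norm(curve.points[other] - curve.points[centre])
        disp = np.linalg.norm(partner.points - curve.points, axis=1)
        assert disp.max() <= 2.0 * separation + 1e-9

    def test_annotations(self, pair):
        curve, partner, _ = pair
        assert partner.knotted is False
        assert partner.knot_core == curve.knot_core

    def test_window_outside_core_rejected(self):
        curve = make_open_trefoil(n_core=40, tail_lengths=(5, 5), seed=0)
        with pytest.raises(ValueError):
            make_unknotted_partner(curve, (0, 3))  # inside a tail
        with pytest.raises(ValueError):
            make_unknotted_partner(curve, (40, 200))


class TestCrossingWindows:
    @pytest.mark.parametrize("n_core", [30, 40, 60, 100])
    def test_three_windows_inside_core(self, n_core):
        c = make_open_trefoil(n_core=n_core, tail_lengths=(5, 5), seed=0)
        windows = crossing_windows(c)
        assert len(windows) == 3
        lo, hi = c.knot_core
        for a, b in windows:
            assert lo <= a <= b <= hi


class TestAddNoise:
    def test_sigma_zero_identity(self):
        c = make_open_trefoil(n_core=40, tail_lengths=(2, 2), seed=0)
        cloud = c.to_cloud()
        noisy = add_noise(cloud, 0.0, seed=5)
        assert noisy.points.tobytes() == cloud.points.tobytes()

    def test_seed_determinism(self):
        c = make_open_trefoil(n_core=40, tail_lengths=(2, 2), seed=0)
        a = add_noise(c.to_cloud(), 0.5, seed=9)
        b = add_noise(c.to_cloud(), 0.5, seed=9)
        assert a.points.tobytes() == b.points.tobytes()

    def test_sample_standard_deviation(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10_000, 3)) * 10
        cloud = PointCloud(points=pts,
                           segment_index=np.minimum(np.arange(10_000), 9_998),
                           fraction=np.zeros(10_000))
        noisy = add_noise(cloud, 1.0, seed=3)
        delta = noisy.points - cloud.points
        for axis in range(3):
            assert 0.97 <= delta[:, axis].std() <= 1.03

    def test_negative_sigma_rejected(self):
        c = make_open_trefoil(n_core=40, tail_lengths=(2, 2), seed=0)
        with pytest.raises(ValueError):
            add_noise(c.to_cloud(), -0.1, seed=0)

    def test_provenance_preserved(self):
        c = make_open_trefoil(n_core=40, tail_lengths=(2, 2), seed=0)
        cloud = c.to_cloud()
        noisy = add_noise(cloud, 0.3, seed=1)
        np.testing.assert_array_equal(noisy.segment_index, cloud.segment_index)
        np.testing.assert_array_equal(noisy.fraction, cloud.fraction)
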