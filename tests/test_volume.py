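"""Volume-estimation tests: hulls, alpha shapes, minimal alpha, grouping."""

import numpy as np
import pytest

import olivescan as ov
from olivescan.volume import (AlphaComplex, AlphaSearchError,
                              alpha_shape_volume, compare_runs,
                              convex_hull_volume, find_min_alpha,
                              measure_cloud, segment_tree_groups)


def ball_sample(rng, n, radius=1.0, surface_frac=0.5):
    """Uniform ball sample with a share of points pinned to the surface."""
    n_surf = int(n * surface_frac)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = np.ones(n)
    r[n_surf:] = rng.random(n - n_surf) ** (1 / 3)
    return u * (radius * r)[:, None]


def box_sample(rng, n, dims, surface_frac=0.3):
    pts = rng.uniform(0, 1, size=(n, 3))
    n_surf = int(n * surface_frac)
    axis = rng.integers(0, 3, n_surf)
    side = rng.integers(0, 2, n_surf).astype(float)
    pts[np.arange(n_surf), axis] = side
    return pts * np.asarray(dims)


class TestConvexHull:
    def test_unit_cube_corners(self):
        corners = np.array([(x, y, z) for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        assert convex_hull_volume(corners) == pytest.approx(1.0, abs=1e-12)

    def test_converges_to_box_volume(self, rng):
        pts = box_sample(rng, 20000, (2.0, 1.5, 14.0))
        v = convex_hull_volume(pts)
        assert 0.97 * 42.0 <= v <= 42.0 + 1e-9

    def test_subset_hull_never_larger(self, rng):
        pts = rng.normal(size=(500, 3))
        assert convex_hull_volume(pts[:100]) <= convex_hull_volume(pts) + 1e-12

    def test_coplanar_points_flagged_as_zero(self):
        flat = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2,
                                np.zeros(10)])
        with pytest.warns(UserWarning, match="degenerate|coplanar"):
            assert convex_hull_volume(flat) == 0.0


class TestAlphaShape:
    def test_infinite_alpha_equals_convex_hull(self, rng):
        pts = rng.normal(size=(400, 3))
        v, closed, ncomp = alpha_shape_volume(pts, np.inf)
        assert v == pytest.approx(convex_hull_volume(pts), rel=1e-9)
        assert closed and ncomp == 1

    def test_ball_volume_recovered_within_5_percent(self, rng):
        pts = ball_sample(rng, 4000)
        v, closed, _ = alpha_shape_volume(pts, 0.4)
        assert closed
        assert v == pytest.approx(4 / 3 * np.pi, rel=0.05)

    def test_cuboid_volume_recovered_within_5_percent(self, rng):
        pts = box_sample(rng, 6000, (2.0, 1.0, 1.0))
        v, closed, _ = alpha_shape_volume(pts, 0.35)
        assert closed
        assert v == pytest.approx(2.0, rel=0.05)

    def test_concave_solid_below_convex_hull(self, rng):
        """An L-shaped solid's alpha volume captures the notch the hull cannot."""
        a = box_sample(rng, 4000, (2.0, 1.0, 1.0))
        b = box_sample(rng, 2000, (1.0, 1.0, 1.0)) + [0.0, 0.0, 1.0]
        pts = np.vstack([a, b])
        v_alpha, _, _ = alpha_shape_volume(pts, 0.35)
        v_hull = convex_hull_volume(pts)
        assert v_alpha == pytest.approx(3.0, rel=0.07)
        assert v_alpha < 0.9 * v_hull

    def test_volume_monotone_in_alpha(self, rng):
        pts = ball_sample(rng, 1500)
        ac = AlphaComplex(pts)
        alphas = [0.2, 0.3, 0.5, 0.8, 1.5, np.inf]
        vols = [ac.volume(a) for a in alphas]
        assert all(v1 <= v2 + 1e-12 for v1, v2 in zip(vols, vols[1:]))
        assert vols[-1] <= convex_hull_volume(pts) + 1e-9

    def test_nonpositive_alpha_rejected(self, rng):
        with pytest.raises(ValueError):
            alpha_shape_volume(rng.normal(size=(10, 3)), 0.0)


class TestFindMinAlpha:
    def test_result_is_on_the_search_grid(self, rng):
        pts = ball_sample(rng, 1200)
        a = find_min_alpha(pts, grid_step=0.05, alpha_lo=0.1, alpha_hi=2.0)
        steps = (a - 0.1) / 0.05
        assert steps == pytest.approx(round(steps), abs=1e-9)

    def test_gap_demands_larger_alpha_than_solid(self, rng):
        """Bridging an internal void costs alpha: a split slab closes later."""
        solid = box_sample(rng, 5000, (3.0, 1.0, 1.0))
        gap = solid[(solid[:, 0] < 1.0) | (solid[:, 0] > 2.0)]
        a_solid = find_min_alpha(solid, grid_step=0.05, alpha_lo=0.05,
                                 alpha_hi=3.0)
        a_gap = find_min_alpha(gap, grid_step=0.05, alpha_lo=0.05,
                               alpha_hi=3.0)
        assert a_gap >= a_solid + 0.3

    def test_search_failure_reports_diagnostics(self, rng):
        two_blobs = np.vstack([rng.normal(0, 0.1, (200, 3)),
                               rng.normal(0, 0.1, (200, 3)) + [50, 0, 0]])
        with pytest.raises(AlphaSearchError, match="components"):
            find_min_alpha(two_blobs, alpha_lo=0.1, alpha_hi=1.0)


class TestSegmentTreeGroups:
    def test_contiguous_hedge_is_one_group(self, small_scene):
        cloud = ov.PointCloud(small_scene.points[small_scene.crown_mask])
        assert len(segment_tree_groups(cloud, 1.0)) == 1

    def test_missing_tree_splits_eight_and_two(self):
        """A missing tree 8 of 11 yields an 8-tree and a 2-tree group."""
        scene = ov.generate_hedgerow(ov.SceneConfig(
            seed=5, missing_tree_indices=(8,), ground_point_density=0.0))
        cloud = ov.PointCloud(scene.points[scene.crown_mask],
                              sweep_index=scene.tree_id[scene.crown_mask])
        groups = segment_tree_groups(cloud, 1.0)
        assert len(groups) == 2
        trees_per_group = [set(np.unique(g.sweep_index)) for g in groups]
        assert trees_per_group[0] == set(range(8))
        assert trees_per_group[1] == {9, 10}

    def test_partition_conserves_points(self, small_scene):
        cloud = ov.PointCloud(small_scene.points)
        groups = segment_tree_groups(cloud, 0.2)
        assert sum(len(g) for g in groups) == len(cloud)

    def test_group_volumes_never_exceed_bridged_union(self, rng):
        """Summed per-group volumes stay below the gap-bridging union volume."""
        a = box_sample(rng, 2500, (1.2, 1.0, 1.0))
        b = box_sample(rng, 2500, (1.2, 1.0, 1.0)) + [2.5, 0, 0]
        union = ov.PointCloud(np.vstack([a, b]))
        rep = measure_cloud(union, gap_threshold=1.0,
                            alpha_bracket=(0.05, 5.0))
        assert len(rep.groups) == 2
        v_bridged, _, _ = alpha_shape_volume(union, max(rep.alpha_star, 1.0))
        assert rep.alpha_volume <= v_bridged + 1e-9


class TestCompareRuns:
    def _report(self, alpha_vol, count, transect="t"):
        return ov.VolumeReport(convex_hull_volume=alpha_vol + 10,
                               alpha_volume=alpha_vol, alpha_star=3.0,
                               point_count=count, closed=True,
                               transect_id=transect)

    def test_identical_reports_zero_delta(self):
        ch = compare_runs(self._report(38.63, 1000), self._report(38.63, 1000))
        assert ch.delta_volume == 0.0 and ch.delta_density == 0

    def test_field_style_differencing(self):
        """38.63 vs 37.60 m^3 and 941,169 vs 821,556 points."""
        ch = compare_runs(self._report(38.63, 941_169),
                          self._report(37.60, 821_556))
        assert ch.delta_volume == pytest.approx(1.03, abs=1e-9)
        assert ch.delta_density == 119_613

    def test_mismatched_transects_rejected(self):
        with pytest.raises(ValueError, match="transect"):
            compare_runs(self._report(1, 1, "a"), self._report(1, 1, "b"))
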