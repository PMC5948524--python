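"""Synthetic-scene generator tests: hedgerow layout, pruning, simulators."""

import numpy as np
import pytest

import olivescan as ov
from olivescan.geometry import NO_RETURN, table_pose
from olivescan.scene import (BOX_A_ID, BOX_B_ID, GROUND_ID,
                             simulate_accelerometer)


class TestGenerateHedgerow:
    def test_tree_count_from_spacing(self):
        scene = ov.generate_hedgerow(ov.SceneConfig(transect_length=15.0,
                                                    tree_spacing=1.35, seed=0))
        assert len(scene.crowns) == 11  # floor(15 / 1.35)

    def test_crown_height_honours_mean_with_zero_spread(self):
        cfg = ov.SceneConfig(tree_height_mean=2.5, tree_height_sd=0.0,
                             crown_width_sd=0.0, seed=1)
        scene = ov.generate_hedgerow(cfg)
        for crown in scene.crowns:
            top = scene.points[scene.tree_id == crown.tree_index][:, 2].max()
            assert top == pytest.approx(2.5, abs=0.05)

    def test_same_seed_reproduces_scene_exactly(self):
        cfg = ov.SceneConfig(seed=99)
        a, b = ov.generate_hedgerow(cfg), ov.generate_hedgerow(cfg)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.tree_id, b.tree_id)

    def test_missing_trees_are_omitted_without_shifting_others(self):
        full = ov.generate_hedgerow(ov.SceneConfig(seed=5))
        gap = ov.generate_hedgerow(ov.SceneConfig(seed=5,
                                                  missing_tree_indices=(8,)))
        assert {c.tree_index for c in gap.crowns} == set(range(11)) - {8}
        # remaining trees identical to the full scene
        for tid in (0, 7, 9, 10):
            np.testing.assert_array_equal(gap.points[gap.tree_id == tid],
                                          full.points[full.tree_id == tid])

    def test_reference_boxes_outside_tree_span(self):
        scene = ov.generate_hedgerow(ov.SceneConfig(seed=0))
        a, b = scene.reference_boxes
        assert a.x_max <= 0.0 and b.x_min >= scene.config.transect_length
        assert a.z_max == pytest.approx(0.30)

    def test_all_points_above_ground_and_labelled(self):
        scene = ov.generate_hedgerow(ov.SceneConfig(seed=0))
        assert scene.points[:, 2].min() >= 0.0
        assert set(np.unique(scene.tree_id)) <= (
            set(range(11)) | {BOX_A_ID, BOX_B_ID, GROUND_ID})

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ov.SceneConfig(transect_length=-1.0)


class TestPruneScene:
    def test_zero_fraction_is_identity(self, small_scene):
        out = ov.prune_scene(small_scene, 0.0)
        np.testing.assert_array_equal(out.points, small_scene.points)

    def test_full_fraction_strips_all_crowns(self, small_scene):
        out = ov.prune_scene(small_scene, 1.0)
        assert not np.any(out.tree_id >= 0)
        assert np.sum(out.tree_id == BOX_A_ID) == np.sum(small_scene.tree_id == BOX_A_ID)

    def test_per_tree_rounded_removal_count(self, default_scene):
        frac = 0.05
        out = ov.prune_scene(default_scene, frac)
        for crown in default_scene.crowns:
            n = int(np.sum(default_scene.tree_id == crown.tree_index))
            kept = int(np.sum(out.tree_id == crown.tree_index))
            assert kept == n - round(frac * n)

    def test_outer_shell_mode_removes_largest_radii(self, small_scene):
        out = ov.prune_scene(small_scene, 0.2)
        for crown in small_scene.crowns:
            rho = lambda sc: np.linalg.norm(
                (sc.points[sc.tree_id == crown.tree_index] - crown.center)
                / crown.semi_axes, axis=1)
            assert rho(out).max() <= rho(small_scene).max()
            assert rho(out).max() < np.partition(rho(small_scene), -1)[-1] + 1e-12

    def test_fraction_out_of_range_rejected(self, small_scene):
        with pytest.raises(ValueError):
            ov.prune_scene(small_scene, 1.5)


class TestSimulateLidarPass:
    def test_single_point_direct_hit(self):
        """One point 1 m straight above the sensor returns range 1.000."""
        cfg = ov.SceneConfig(seed=0)
        pose = table_pose(2, "left")
        scene = ov.Scene(np.array([[0.0, -1.5, 2.55]]), np.array([0]),
                         ov.generate_hedgerow(cfg).reference_boxes,
                         (), cfg)
        sweeps = ov.simulate_lidar_pass(scene, pose, noise_sd=0.0, seed=0,
                                        x_start=0.0, travel_distance=0.05)
        beam_up = int(round((90 - (-45)) / 1.0))  # zenith beam for this pose
        assert sweeps[0].ranges[beam_up] == pytest.approx(1.0, abs=1e-9)
        others = np.delete(sweeps[0].ranges, beam_up)
        assert np.all(others == NO_RETURN)

    def test_sweep_count_follows_kinematics(self, small_scene):
        sweeps = ov.simulate_lidar_pass(small_scene, table_pose(1, "left"),
                                        speed=0.556, sweep_rate=50.0,
                                        x_start=0.0, travel_distance=15.0)
        assert len(sweeps) == pytest.approx(15.0 / 0.556 * 50.0, abs=2)

    def test_half_speed_doubles_sweeps(self, small_scene):
        fast = ov.simulate_lidar_pass(small_scene, table_pose(1, "left"),
                                      speed=1.0, x_start=0.0, travel_distance=10.0)
        slow = ov.simulate_lidar_pass(small_scene, table_pose(1, "left"),
                                      speed=0.5, x_start=0.0, travel_distance=10.0)
        assert abs(len(slow) - 2 * len(fast)) <= 2

    def test_final_encoder_count_matches_travel(self, small_scene):
        sweeps = ov.simulate_lidar_pass(small_scene, table_pose(1, "left"),
                                        encoder_resolution=0.003,
                                        x_start=0.0, travel_distance=15.0)
        assert sweeps[-1].encoder_count == 5000
        counts = [s.encoder_count for s in sweeps]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_empty_scene_yields_all_sentinels(self):
        cfg = ov.SceneConfig(seed=0)
        boxes = ov.generate_hedgerow(cfg).reference_boxes
        scene = ov.Scene(np.empty((0, 3)), np.empty(0, dtype=int), boxes, (), cfg)
        sweeps = ov.simulate_lidar_pass(scene, table_pose(1, "left"),
                                        x_start=0.0, travel_distance=1.0)
        assert all(np.all(s.ranges == NO_RETURN) for s in sweeps)

    def test_same_seed_reproduces_pass(self, small_scene):
        a = ov.simulate_lidar_pass(small_scene, table_pose(1, "left"), seed=7)
        b = ov.simulate_lidar_pass(small_scene, table_pose(1, "left"), seed=7)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.ranges, sb.ranges)


class TestSimulateAccelerometer:
    def test_amplitude_clipped_at_sensor_limit(self):
        log = simulate_accelerometer(20.0, 2.0, seed=1)
        mag = np.linalg.norm(log[["x_counts", "y_counts", "z_counts"]]
                             .to_numpy() / 2048.0, axis=1)
        assert mag.max() <= 16.0 + 0.1
        assert mag.max() >= 15.8

    def test_one_g_is_2048_counts(self):
        log = simulate_accelerometer(7.0, 2.0, noise_sd=0.0, seed=2)
        quiescent = log.iloc[:100][["x_counts", "y_counts", "z_counts"]].to_numpy()
        mag_counts = np.linalg.norm(quiescent, axis=1)
        assert np.median(mag_counts) == pytest.approx(2048, abs=2)

    def test_supra_threshold_extent_matches_duration(self):
        log = simulate_accelerometer(7.21, 4.81, sample_rate=100.0,
                                     noise_sd=0.0, seed=3)
        mag = np.linalg.norm(log[["x_counts", "y_counts", "z_counts"]]
                             .to_numpy() / 2048.0, axis=1)
        n_above = int(np.sum(mag >= 2.0))
        assert abs(n_above - 481) <= 2

    def test_deterministic_per_seed(self):
        a = simulate_accelerometer(5.0, 3.0, seed=9)
        b = simulate_accelerometer(5.0, 3.0, seed=9)
        assert a.equals(b)
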