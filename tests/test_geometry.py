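"""Scan-geometry unit tests: polar conversion, mounting rotations, odometry."""

import numpy as np
import pytest

import olivescan as ov
from olivescan.geometry import (ANGULAR_STEP, DEFAULT_FOV_START, N_BEAMS,
                                NO_RETURN, beam_angles, build_cloud,
                                polar_to_cartesian, rotation_matrix,
                                table_pose)


class TestPolarToCartesian:
    def test_beam_at_angle_zero_points_along_sensor_x(self):
        ranges = np.full(N_BEAMS, NO_RETURN)
        i_zero = int(round(-DEFAULT_FOV_START / ANGULAR_STEP))  # beam at 0 rad
        ranges[i_zero] = 1.0
        pts, idx = polar_to_cartesian(ranges)
        assert idx.tolist() == [i_zero]
        np.testing.assert_allclose(pts[0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_beam_at_quarter_turn_points_along_sensor_y(self):
        ranges = np.full(N_BEAMS, NO_RETURN)
        i_90 = int(round((np.pi / 2 - DEFAULT_FOV_START) / ANGULAR_STEP))
        ranges[i_90] = 2.0
        pts, _ = polar_to_cartesian(ranges)
        np.testing.assert_allclose(pts[0], [0.0, 2.0, 0.0], atol=1e-12)

    def test_fov_spans_exactly_270_degrees(self):
        g = beam_angles()
        assert g[-1] - g[0] == pytest.approx(np.deg2rad(270.0), abs=1e-12)

    def test_operational_range_gate(self):
        ranges = np.full(N_BEAMS, NO_RETURN)
        ranges[:4] = [0.3, 0.5, 19.99, 20.5]  # below min, at min, in, above max
        pts, idx = polar_to_cartesian(ranges)
        assert idx.tolist() == [2]

    def test_wrong_beam_count_rejected(self):
        with pytest.raises(ValueError, match="271"):
            polar_to_cartesian(np.ones(270))


class TestMountingRotations:
    # hand-computed images of the sensor axes under each reference mounting
    HAND_COMPUTED = {
        (1, "left"): [[0, 0, 1], [0, 1, 0], [-1, 0, 0]],
        (1, "right"): [[0, 0, -1], [0, 1, 0], [1, 0, 0]],
        (2, "left"): [[0, 0, 1], [1, 0, 0], [0, 1, 0]],
        (2, "right"): [[0, 0, -1], [-1, 0, 0], [0, 1, 0]],
    }

    @pytest.mark.parametrize("sensor,side", [(1, "left"), (1, "right"),
                                             (2, "left"), (2, "right")])
    def test_reference_poses_match_hand_computed_matrices(self, sensor, side):
        pose = table_pose(sensor, side)
        np.testing.assert_allclose(pose.rotation,
                                   self.HAND_COMPUTED[(sensor, side)],
                                   atol=1e-12)

    @pytest.mark.parametrize("sensor,side", [(1, "left"), (1, "right"),
                                             (2, "left"), (2, "right")])
    def test_all_mountings_scan_the_row_cross_section(self, sensor, side):
        """Every beam must land in the vehicle (y, z) plane."""
        pose = table_pose(sensor, side)
        g = beam_angles(pose.fov_start)
        dirs = np.column_stack([np.cos(g), np.sin(g), np.zeros_like(g)])
        rotated = dirs @ pose.rotation.T
        assert np.abs(rotated[:, 0]).max() < 1e-9

    def test_identity_pose_only_lifts_by_mount_height(self, rng):
        pose = ov.SensorPose(0.0, 0.0, 0.0, mount_height=1.55)
        pts = rng.normal(size=(50, 3))
        out = ov.apply_orientation(pts, pose)
        np.testing.assert_allclose(out - [0, 0, 1.55], pts, atol=1e-12)

    def test_orientation_round_trip(self, rng):
        pose = ov.SensorPose(0.3, -1.1, 2.0, mount_height=1.0)
        pts = rng.normal(size=(100, 3))
        out = ov.apply_orientation(pts, pose)
        back = (out - [0, 0, pose.mount_height]) @ pose.rotation
        np.testing.assert_allclose(back, pts, atol=1e-12)

    def test_rotations_preserve_pairwise_distances(self, rng):
        r = rotation_matrix(*rng.uniform(-np.pi, np.pi, 3))
        pts = rng.normal(size=(40, 3))
        d_before = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        rp = pts @ r.T
        d_after = np.linalg.norm(rp[:, None] - rp[None], axis=-1)
        np.testing.assert_allclose(d_after, d_before, atol=1e-9)


class TestOdometry:
    def test_zero_count_is_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(ov.apply_odometry(pts, 0, 0.003), pts)

    def test_reference_resolution_shift(self):
        pts = np.zeros((1, 3))
        out = ov.apply_odometry(pts, 5000, 0.003)
        assert out[0, 0] == pytest.approx(15.0)

    def test_shift_linear_in_resolution(self, rng):
        pts = rng.normal(size=(5, 3))
        a = ov.apply_odometry(pts, 1234, 0.003)
        b = ov.apply_odometry(pts, 1234, 0.006)
        np.testing.assert_allclose(b[:, 0] - pts[:, 0],
                                   2 * (a[:, 0] - pts[:, 0]), atol=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="rollback"):
            ov.apply_odometry(np.zeros((1, 3)), -1, 0.003)


class TestBuildCloud:
    def test_all_sentinel_sweeps_give_empty_cloud(self):
        sweeps = [ov.SweepRecord(0.0, 0, np.full(N_BEAMS, NO_RETURN))
                  for _ in range(5)]
        cloud = build_cloud(sweeps, table_pose(1, "left"))
        assert len(cloud) == 0

    def test_empty_sweep_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_cloud([], table_pose(1, "left"))

    def test_point_count_bounded_by_beam_budget(self, small_scene):
        pose = table_pose(1, "left")
        sweeps = ov.simulate_lidar_pass(small_scene, pose, seed=3)
        cloud = build_cloud(sweeps, pose)
        assert 0 < len(cloud) <= len(sweeps) * N_BEAMS
        assert cloud.sensor_id is not None and set(cloud.sensor_id) == {1}
        assert set(cloud.side) == {"left"}

    def test_x_extent_tracks_encoder_span(self, small_scene):
        pose = table_pose(1, "left")
        sweeps = ov.simulate_lidar_pass(small_scene, pose, seed=3)
        cloud = build_cloud(sweeps, pose)
        encoder_span = sweeps[-1].encoder_count * 0.003
        assert cloud.points[:, 0].min() >= -ov.geometry.RANGE_MAX
        assert cloud.points[:, 0].max() <= encoder_span + ov.geometry.RANGE_MAX

    def test_reconstruction_matches_scene_within_bin_arc(self, small_scene):
        """Noise-free simulate->rebuild lands points on the scene surface.

        The residual budget is one angular-bin arc at the typical ~2 m
        working range plus the simulator's scan-slab half-thickness.
        """
        from scipy.spatial import cKDTree
        pose = table_pose(1, "left")
        sweeps = ov.simulate_lidar_pass(small_scene, pose, noise_sd=0.0, seed=3)
        cloud = build_cloud(sweeps, pose)
        box_a = small_scene.reference_boxes[0]
        shifted = cloud.points + [box_a.x_min - 0.5, -1.5, 0.0]
        d, _ = cKDTree(small_scene.points).query(shifted)
        budget = 2.0 * ANGULAR_STEP + 0.01
        assert d.mean() < budget
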