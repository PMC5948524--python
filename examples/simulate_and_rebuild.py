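"""Simulate a LiDAR pass along a synthetic hedgerow and rebuild the cloud.

Generates an 11-tree transect, drives the sideways scanner down its left
side at 2 km/h, and reassembles the sweeps into a 3D cloud via the
polar-to-Cartesian / mounting-rotation / encoder-translation chain.  The
final figure is the mean distance from reconstructed points back to the
ground-truth scene: it should sit near the 1 cm range noise, confirming the
odometry-fused geometry is right.
"""

import numpy as np
from scipy.spatial import cKDTree

import olivescan as ov

scene = ov.generate_hedgerow(ov.SceneConfig(seed=42))
print(f"scene: {len(scene.crowns)} trees, {len(scene)} ground-truth points")

pose = ov.table_pose(sensor_id=1, side="left")
sweeps = ov.simulate_lidar_pass(scene, pose, speed=0.556, sweep_rate=50.0,
                                noise_sd=0.01, seed=1)
print(f"pass: {len(sweeps)} sweeps, final encoder count "
      f"{sweeps[-1].encoder_count} (3 mm/pulse)")

cloud = ov.build_cloud(sweeps, pose, resolution=0.003)
print(f"cloud: {len(cloud)} points")

# the raw cloud lives in the sensor-track frame; shift by the known pass
# start and sensor offset to compare against the scene
offset = np.array([scene.reference_boxes[0].x_min - 0.5, -1.5, 0.0])
d, _ = cKDTree(scene.points).query(cloud.points + offset)
print(f"mean cloud->scene distance: {d.mean() * 100:.1f} cm "
      f"(range noise was 1.0 cm)")
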