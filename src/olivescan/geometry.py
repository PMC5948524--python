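"""Scan geometry: raw 2D LiDAR sweeps to a 3D point cloud in the row frame.

A SICK LMS111-class scanner as logged here measures ranges in 271
directions spanning a 270 degree field of view (1 degree between recorded
beams).  Each sweep is a planar polar
scan; the sensor is mounted on a moving platform, so successive sweeps are
laid out along the travel direction using a wheel-encoder odometer
(3 mm per pulse in the reference configuration).

Frames and conventions
----------------------
* Sensor frame: beams lie in the sensor's native (x, y) plane; beam ``i``
  points along ``(cos g_i, sin g_i, 0)`` with ``g_i = fov_start + i * step``.
* Vehicle/row frame: ``x`` = travel direction, ``z`` = up, origin on the
  ground at the start of the pass.  The mounting orientation is described by
  roll/pitch/yaw applied as ``R = Rz(yaw) @ Ry(pitch) @ Rx(roll)``; with the
  reference mounting angles every beam lands in the vertical (y, z)
  cross-section plane, which is what a side- or upward-facing scanner on a
  tractor sweeps.  The mount height is added to ``z`` after rotation and the
  encoder distance to ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

N_BEAMS = 271
FOV_SPAN = np.deg2rad(270.0)
#: 271 beams spanning exactly 270 degrees: 1 degree between adjacent beams
ANGULAR_STEP = FOV_SPAN / (N_BEAMS - 1)
DEFAULT_FOV_START = np.deg2rad(-45.0)
#: operational range gate (m): returns outside (0.5, 20] are dropped
RANGE_MIN = 0.5
RANGE_MAX = 20.0
#: sentinel stored in sweep logs for beams with no return (beyond max range)
NO_RETURN = 21.0

__all__ = [
    "N_BEAMS",
    "ANGULAR_STEP",
    "DEFAULT_FOV_START",
    "RANGE_MIN",
    "RANGE_MAX",
    "NO_RETURN",
    "SensorPose",
    "SweepRecord",
    "PointCloud",
    "rotation_matrix",
    "table_pose",
    "beam_angles",
    "polar_to_cartesian",
    "apply_orientation",
    "apply_odometry",
    "build_cloud",
]


def rotation_matrix(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Rotation ``R = Rz(yaw) @ Ry(pitch) @ Rx(roll)`` (intrinsic z-y-x)."""
    cr, sr = np.cos(roll), np.sin(roll)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cy, sy = np.cos(yaw), np.sin(yaw)
    rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass(frozen=True)
class SensorPose:
    """Mounting pose of one scanner.

    ``sensor_id`` 1 is the sideways-facing unit, 2 the upward-facing unit.
    Angles are radians; ``mount_height`` metres above ground.  ``fov_start``
    is the direction of beam 0 in the sensor scan plane; the 90 degree blind
    cone sits opposite the middle of the field of view.
    """

    roll: float
    pitch: float
    yaw: float
    mount_height: float = 1.55
    sensor_id: int = 1
    side: str = "left"
    fov_start: float = DEFAULT_FOV_START

    def __post_init__(self) -> None:
        if self.mount_height <= 0:
            raise ValueError("mount_height must be positive")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.sensor_id not in (1, 2):
            raise ValueError(f"sensor_id must be 1 or 2, got {self.sensor_id!r}")

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.roll, self.pitch, self.yaw)


#: reference mounting angles (roll, pitch, yaw) per (sensor_id, side)
_TABLE_ANGLES = {
    (1, "left"): (0.0, np.pi / 2, 0.0),
    (1, "right"): (0.0, -np.pi / 2, 0.0),
    (2, "left"): (np.pi / 2, 0.0, np.pi / 2),
    (2, "right"): (np.pi / 2, 0.0, -np.pi / 2),
}


def table_pose(sensor_id: int, side: str, mount_height: float = 1.55) -> SensorPose:
    """Reference mounting pose for one of the four scanner configurations.

    The sideways unit scanning the right side is remounted rotated half a
    turn about its scan axis (``fov_start`` 135 degrees) so that its blind
    cone keeps facing away from the row; all other configurations use the
    default −45 degree start.
    """
    roll, pitch, yaw = _TABLE_ANGLES[(sensor_id, side)]
    fov_start = np.deg2rad(135.0) if (sensor_id, side) == (1, "right") else DEFAULT_FOV_START
    return SensorPose(roll, pitch, yaw, mount_height=mount_height,
                      sensor_id=sensor_id, side=side, fov_start=fov_start)


@dataclass
class SweepRecord:
    """One scanner revolution: timestamp, cumulative encoder count, 271 ranges."""

    timestamp: float
    encoder_count: int
    ranges: np.ndarray

    def __post_init__(self) -> None:
        self.ranges = np.asarray(self.ranges, dtype=float)
        if self.ranges.shape != (N_BEAMS,):
            raise ValueError(
                f"expected {N_BEAMS} ranges per sweep, got {self.ranges.shape}"
            )


@dataclass
class PointCloud:
    """N x 3 points (m) with per-point provenance metadata."""

    points: np.ndarray
    sensor_id: np.ndarray | None = None
    side: np.ndarray | None = None
    sweep_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        n = len(self.points)
        for name in ("sensor_id", "side", "sweep_index"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if len(v) != n:
                    raise ValueError(f"{name} length {len(v)} != point count {n}")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset cloud by boolean mask or index array, keeping metadata."""
        sub = {}
        for name in ("sensor_id", "side", "sweep_index"):
            v = getattr(self, name)
            sub[name] = None if v is None else v[mask]
        return PointCloud(self.points[mask], **sub)

    @staticmethod
    def concatenate(clouds: Sequence["PointCloud"]) -> "PointCloud":
        pts = np.vstack([c.points for c in clouds]) if clouds else np.empty((0, 3))
        meta = {}
        for name in ("sensor_id", "side", "sweep_index"):
            vals = [getattr(c, name) for c in clouds]
            if clouds and all(v is not None for v in vals):
                meta[name] = np.concatenate(vals)
            else:
                meta[name] = None
        return PointCloud(pts, **meta)


def beam_angles(fov_start: float = DEFAULT_FOV_START,
                n_beams: int = N_BEAMS,
                step: float = ANGULAR_STEP) -> np.ndarray:
    """Beam directions (rad) in the sensor scan plane, beam 0 first."""
    return fov_start + step * np.arange(n_beams)


def polar_to_cartesian(ranges: np.ndarray,
                       angular_step: float = ANGULAR_STEP,
                       fov_start: float = DEFAULT_FOV_START,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Convert one sweep's ranges to sensor-frame points.

    Ranges outside the operational gate (0.5, 20] m — including the
    no-return sentinel — are dropped.  Returns ``(points, beam_index)`` where
    ``points[k] = r * (cos g, sin g, 0)`` for the retained beams.
    """
    ranges = np.asarray(ranges, dtype=float)
    if ranges.shape != (N_BEAMS,):
        raise ValueError(f"expected {N_BEAMS} ranges, got shape {ranges.shape}")
    keep = (ranges > RANGE_MIN) & (ranges <= RANGE_MAX)
    idx = np.nonzero(keep)[0]
    g = fov_start + angular_step * idx
    r = ranges[idx]
    pts = np.column_stack([r * np.cos(g), r * np.sin(g), np.zeros_like(r)])
    return pts, idx


def apply_orientation(points: np.ndarray, pose: SensorPose) -> np.ndarray:
    """Rotate sensor-frame points into the vehicle frame and lift by mount height."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    out = pts @ pose.rotation.T
    out[:, 2] += pose.mount_height
    return out


def apply_odometry(points: np.ndarray, encoder_count: int,
                   resolution: float) -> np.ndarray:
    """Translate points along x by the encoder-measured travel distance."""
    if resolution <= 0:
        raise ValueError("encoder resolution must be positive")
    if encoder_count < 0:
        raise ValueError("negative encoder count: wheel rollback unsupported")
    out = np.array(points, dtype=float).reshape(-1, 3)
    out[:, 0] += encoder_count * resolution
    return out


def build_cloud(sweeps: Iterable[SweepRecord], pose: SensorPose,
                resolution: float = 0.003) -> PointCloud:
    """Assemble a full pass of sweeps into one row-frame point cloud.

    Composition of :func:`polar_to_cartesian`, :func:`apply_orientation` and
    :func:`apply_odometry` over every sweep; each point carries the sensor
    id, scan side and sweep index it came from.
    """
    sweeps = list(sweeps)
    if not sweeps:
        raise ValueError("empty sweep list")
    chunks: list[np.ndarray] = []
    sweep_idx: list[np.ndarray] = []
    for i, sw in enumerate(sweeps):
        pts, _ = polar_to_cartesian(sw.ranges, fov_start=pose.fov_start)
        if len(pts) == 0:
            continue
        pts = apply_orientation(pts, pose)
        pts = apply_odometry(pts, sw.encoder_count, resolution)
        chunks.append(pts)
        sweep_idx.append(np.full(len(pts), i, dtype=np.int32))
    if not chunks:
        return PointCloud(np.empty((0, 3)),
                          sensor_id=np.empty(0, dtype=np.int8),
                          side=np.empty(0, dtype="U5"),
                          sweep_index=np.empty(0, dtype=np.int32))
    pts = np.vstack(chunks)
    n = len(pts)
    return PointCloud(
        pts,
        sensor_id=np.full(n, pose.sensor_id, dtype=np.int8),
        side=np.full(n, pose.side, dtype="U5"),
        sweep_index=np.concatenate(sweep_idx),
    )
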