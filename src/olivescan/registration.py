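"""Rigid alignment of point clouds on fixed-reference correspondences.

Clouds from the left and right passes, and from before/after harvest, are
brought into one frame by least-squares rigid (Kabsch) alignment on manually
identified corners of the fixed reference boxes.  The fit RMS is reported
and gated against the 3 cm ceiling maintained in the field workflow; merging
refuses transforms above the gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import PointCloud

DEFAULT_RMS_GATE = 0.03  # m

__all__ = [
    "RigidTransform",
    "AlignmentError",
    "DegenerateGeometryError",
    "estimate_rigid_transform",
    "apply_transform",
    "merge_aligned",
    "DEFAULT_RMS_GATE",
]


class DegenerateGeometryError(ValueError):
    """Raised when correspondences cannot determine a rigid transform."""


class AlignmentError(RuntimeError):
    """Raised when an alignment fails its quality gate."""


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation (optionally uniform scale) with its fit RMS."""

    rotation: np.ndarray
    translation: np.ndarray
    rms_error: float
    n_correspondences: int
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float).reshape(3))
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rms_error < 0:
            raise ValueError("rms_error must be non-negative")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0, 0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return self.scale * (pts @ self.rotation.T) + self.translation

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.T
        s_inv = 1.0 / self.scale
        return RigidTransform(r_inv, -s_inv * (r_inv @ self.translation),
                              self.rms_error, self.n_correspondences, s_inv)


def estimate_rigid_transform(src: np.ndarray, dst: np.ndarray,
                             allow_scale: bool = False) -> RigidTransform:
    """Least-squares rigid (or similarity) transform mapping ``src`` onto ``dst``.

    Kabsch/Procrustes solution: optimal rotation from the SVD of the
    cross-covariance of the centred point sets, translation from the
    centroids; with ``allow_scale`` the uniform Procrustes scale is also
    estimated (clouds from a calibrated odometer should be metric, so rigid
    is the default).  Requires at least 3 non-collinear correspondence pairs.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    if src.shape != dst.shape:
        raise ValueError("src and dst must have the same shape")
    k = len(src)
    if k < 3:
        raise DegenerateGeometryError(f"need >= 3 correspondences, got {k}")
    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    src_c = src - c_src
    dst_c = dst - c_dst
    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        raise DegenerateGeometryError("correspondences are (nearly) collinear")

    rot, _ = Rotation.align_vectors(dst_c, src_c)
    r = rot.as_matrix()
    if allow_scale:
        scale = float(np.sum(dst_c * (src_c @ r.T)) / np.sum(src_c ** 2))
    else:
        scale = 1.0
    t = c_dst - scale * (r @ c_src)
    resid = scale * (src_c @ r.T) - dst_c
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return RigidTransform(r, t, rms, k, scale)


def apply_transform(cloud: PointCloud, transform: RigidTransform) -> PointCloud:
    """Map every point of ``cloud`` by the transform; metadata preserved."""
    return PointCloud(transform.apply(cloud.points),
                      sensor_id=cloud.sensor_id, side=cloud.side,
                      sweep_index=cloud.sweep_index)


def merge_aligned(left: PointCloud, right: PointCloud,
                  t_right_to_left: RigidTransform,
                  rms_gate: float = DEFAULT_RMS_GATE) -> PointCloud:
    """Union of ``left`` and the transformed ``right`` cloud.

    Refuses to merge if the transform's fit RMS exceeds ``rms_gate``
    (default 3 cm, the alignment ceiling maintained in the field).
    """
    if t_right_to_left.rms_error > rms_gate:
        raise AlignmentError(
            f"alignment RMS {t_right_to_left.rms_error * 100:.2f} cm exceeds "
            f"gate {rms_gate * 100:.2f} cm; refusing to merge")
    return PointCloud.concatenate([left, apply_transform(right, t_right_to_left)])
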