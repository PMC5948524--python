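"""Region-of-interest cropping: coordinate pre-filter, box-anchored ROI, ground removal.

The study region is anchored on the two fixed reference boxes: the crop
keeps points between the boxes' upper inner corners (nominally 0.30 m above
ground) and their vertical projections, which removes both the ground
returns and the box points themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import PointCloud

NOMINAL_Z_FLOOR = 0.30
Z_FLOOR_TOLERANCE = 0.02

__all__ = ["ROI", "coordinate_limit_filter", "roi_from_boxes", "crop_roi",
           "NOMINAL_Z_FLOOR"]


@dataclass(frozen=True)
class ROI:
    """Crop region: x between the inner box faces, z above the box-top floor."""

    x_min: float
    x_max: float
    z_floor: float = NOMINAL_Z_FLOOR
    z_max: float = 21.55
    y_min: float = -np.inf
    y_max: float = np.inf

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError("x_min must be < x_max")
        if not self.z_floor < self.z_max:
            raise ValueError("z_floor must be < z_max")

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k))
                for k in ("x_min", "x_max", "z_floor", "z_max", "y_min", "y_max")}


def coordinate_limit_filter(cloud: PointCloud, y_max: float,
                            z_max: float) -> PointCloud:
    """Pre-filter: keep points with |y| <= y_max and z <= z_max.

    Used on raw clouds to strip the neighbouring row and far returns before
    alignment (row spacing 3.75 m puts the next row well outside a ~2 m
    lateral limit).
    """
    if y_max <= 0 or z_max <= 0:
        raise ValueError("filter limits must be positive")
    pts = cloud.points
    mask = (np.abs(pts[:, 1]) <= y_max) & (pts[:, 2] <= z_max)
    return cloud.select(mask)


def roi_from_boxes(box_a_corner: np.ndarray, box_b_corner: np.ndarray,
                   z_max: float = 21.55,
                   y_min: float = -np.inf, y_max: float = np.inf) -> ROI:
    """Build the ROI from one upper inner corner of each reference box.

    The x span runs between the corners; the crop floor is the corner
    height.  A warning is issued if the corner height deviates from the
    nominal 0.30 m by more than 2 cm (field boxes may vary, but a large
    deviation usually means the wrong corner was picked).
    """
    a = np.asarray(box_a_corner, dtype=float).reshape(3)
    b = np.asarray(box_b_corner, dtype=float).reshape(3)
    if abs(a[0] - b[0]) < 1e-9:
        raise ValueError("box corners share the same x: degenerate ROI")
    z_floor = float((a[2] + b[2]) / 2.0)
    if abs(z_floor - NOMINAL_Z_FLOOR) > Z_FLOOR_TOLERANCE:
        warnings.warn(
            f"reference corner height {z_floor:.3f} m deviates from the "
            f"nominal {NOMINAL_Z_FLOOR:.2f} m by more than "
            f"{Z_FLOOR_TOLERANCE * 100:.0f} cm", stacklevel=2)
    return ROI(x_min=float(min(a[0], b[0])), x_max=float(max(a[0], b[0])),
               z_floor=z_floor, z_max=z_max, y_min=y_min, y_max=y_max)


def crop_roi(cloud: PointCloud, roi: ROI) -> PointCloud:
    """Crop to the ROI: x in [x_min, x_max], z in (z_floor, z_max], y in limits.

    The z interval is half-open at the floor so that points exactly at the
    box-top height count as ground and are dropped (deterministic
    tie-break).  An empty result is allowed (warning only).
    """
    pts = cloud.points
    mask = ((pts[:, 0] >= roi.x_min) & (pts[:, 0] <= roi.x_max)
            & (pts[:, 2] > roi.z_floor) & (pts[:, 2] <= roi.z_max)
            & (pts[:, 1] >= roi.y_min) & (pts[:, 1] <= roi.y_max))
    out = cloud.select(mask)
    if len(out) == 0:
        warnings.warn("ROI crop produced an empty cloud", stacklevel=2)
    return out
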