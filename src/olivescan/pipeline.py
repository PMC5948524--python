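"""End-to-end transect pipeline: sweeps -> clouds -> alignment -> ROI -> volumes.

One monitored transect yields eight independent point clouds: 2 scanners
(sideways / upward) x 2 scan sides (left / right) x before/after harvest.
Per scanner and phase the pipeline builds both side clouds from the sweep
logs, pre-filters them, aligns each onto the row frame using reference-box
corner correspondences (3 cm RMS gate), merges the sides, crops to the
box-anchored region of interest, and measures convex-hull and minimal-alpha
alpha-shape volumes.  Before-minus-after differences per scanner are the
harvest-induced canopy volume and point-density losses.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import io as osio
from .geometry import PointCloud, SensorPose, SweepRecord, build_cloud, table_pose
from .registration import (DEFAULT_RMS_GATE, AlignmentError, apply_transform,
                           estimate_rigid_transform, merge_aligned)
from .roi import coordinate_limit_filter, crop_roi, roi_from_boxes
from .volume import (DEFAULT_ALPHA_BRACKET, DEFAULT_ALPHA_STEP,
                     DEFAULT_GAP_THRESHOLD, VolumeReport, compare_runs,
                     measure_cloud)

PHASES = ("before", "after")
SIDES = ("left", "right")
SENSORS = (1, 2)

__all__ = ["PipelineSettings", "RunConfig", "load_config", "save_config",
           "run_transect", "run_from_config", "report_to_dict",
           "PHASES", "SIDES", "SENSORS"]


@dataclass(frozen=True)
class PipelineSettings:
    """Tunable processing parameters with the field-campaign defaults."""

    encoder_resolution: float = 0.003   # m per odometry pulse
    mount_height: float = 1.55          # m above ground
    prefilter_y_max: float = 2.0        # m: strips the neighbouring row (3.75 m away)
    prefilter_z_max: float = 8.0        # m: well above any hedgerow
    rms_gate: float = DEFAULT_RMS_GATE  # m: alignment quality ceiling
    alpha: float | str = "auto"         # fixed alpha (m) or minimal-alpha search
    alpha_step: float = DEFAULT_ALPHA_STEP
    alpha_lo: float = DEFAULT_ALPHA_BRACKET[0]
    alpha_hi: float = DEFAULT_ALPHA_BRACKET[1]
    gap_threshold: float = DEFAULT_GAP_THRESHOLD
    allow_scale: bool = False


def assemble_sensor_phase(sweeps_by_side: Mapping[str, list[SweepRecord]],
                          poses_by_side: Mapping[str, SensorPose],
                          corr_by_side: Mapping[str, tuple[np.ndarray, np.ndarray]],
                          settings: PipelineSettings = PipelineSettings(),
                          ) -> tuple[PointCloud, dict]:
    """Build, pre-filter, align and merge the two side clouds of one scan.

    Each side's cloud is aligned onto the row frame with its own
    reference-corner correspondences; both alignments must pass the RMS
    gate.  Returns the merged row-frame cloud and per-side diagnostics.
    """
    clouds = {}
    transforms = {}
    for side in SIDES:
        cloud = build_cloud(sweeps_by_side[side], poses_by_side[side],
                            settings.encoder_resolution)
        cloud = coordinate_limit_filter(cloud, settings.prefilter_y_max,
                                        settings.prefilter_z_max)
        src, dst = corr_by_side[side]
        transforms[side] = estimate_rigid_transform(src, dst,
                                                    allow_scale=settings.allow_scale)
        clouds[side] = cloud
    t_left, t_right = transforms["left"], transforms["right"]
    if t_left.rms_error > settings.rms_gate:
        raise AlignmentError(
            f"left alignment RMS {t_left.rms_error * 100:.2f} cm exceeds gate")
    merged = merge_aligned(apply_transform(clouds["left"], t_left),
                           clouds["right"], t_right, settings.rms_gate)
    info = {side: {"n_points": len(clouds[side]),
                   "rms_error_m": transforms[side].rms_error,
                   "n_correspondences": transforms[side].n_correspondences}
            for side in SIDES}
    return merged, info


def run_transect(sweeps: Mapping[tuple[int, str, str], list[SweepRecord]],
                 poses: Mapping[tuple[int, str], SensorPose],
                 correspondences: Mapping[tuple[int, str, str],
                                          tuple[np.ndarray, np.ndarray]],
                 roi_corner_a: np.ndarray, roi_corner_b: np.ndarray,
                 settings: PipelineSettings = PipelineSettings(),
                 transect_id: str = "transect") -> dict:
    """Process one transect's eight sweep logs into per-sensor change reports.

    ``sweeps`` and ``correspondences`` are keyed by ``(sensor_id, side,
    phase)`` with phase in ``("before", "after")``; ``poses`` by
    ``(sensor_id, side)``.  Returns a nested result dictionary with, per
    sensor, the before/after volume reports and the change report
    (including per-side point-count deltas).
    """
    roi = roi_from_boxes(roi_corner_a, roi_corner_b, z_max=settings.prefilter_z_max)
    result = {"transect_id": transect_id, "roi": roi.to_dict(),
              "settings": _settings_dict(settings), "sensors": {}}
    for sensor in SENSORS:
        phase_reports: dict[str, VolumeReport] = {}
        side_counts: dict[str, dict[str, int]] = {}
        align_info: dict[str, dict] = {}
        for phase in PHASES:
            merged, info = assemble_sensor_phase(
                {s: sweeps[(sensor, s, phase)] for s in SIDES},
                {s: poses[(sensor, s)] for s in SIDES},
                {s: correspondences[(sensor, s, phase)] for s in SIDES},
                settings)
            cropped = crop_roi(merged, roi)
            phase_reports[phase] = measure_cloud(
                cropped, alpha=settings.alpha, grid_step=settings.alpha_step,
                alpha_bracket=(settings.alpha_lo, settings.alpha_hi),
                gap_threshold=settings.gap_threshold,
                transect_id=transect_id, sensor_id=sensor, label=phase)
            side_counts[phase] = {
                s: int(np.sum(cropped.side == s)) if cropped.side is not None else 0
                for s in SIDES}
            align_info[phase] = info
        change = compare_runs(phase_reports["before"], phase_reports["after"],
                              per_side_counts=(side_counts["before"],
                                               side_counts["after"]))
        result["sensors"][sensor] = {
            "before": phase_reports["before"],
            "after": phase_reports["after"],
            "change": change,
            "alignment": align_info,
        }
    return result


def report_to_dict(result: dict) -> dict:
    """Convert a run_transect result into a JSON-serialisable report."""
    out = {k: v for k, v in result.items() if k != "sensors"}
    out["sensors"] = {}
    for sensor, block in result["sensors"].items():
        out["sensors"][str(sensor)] = {
            "before": block["before"].to_dict(),
            "after": block["after"].to_dict(),
            "change": block["change"].to_dict(),
            "alignment": block["alignment"],
        }
    return out


def _settings_dict(settings: PipelineSettings) -> dict:
    return asdict(settings)


# ---------------------------------------------------------------------------
# run configuration files

_LOG_KEYS = tuple(f"sensor{s}_{side}_{phase}"
                  for s in SENSORS for side in SIDES for phase in PHASES)

_ALLOWED_TOP_KEYS = {
    "transect_id", "scan_logs", "correspondences", "roi", "settings",
    "seed", "output_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for the file-driven pipeline."""

    transect_id: str
    scan_logs: dict
    correspondences: dict
    roi_corner_a: tuple
    roi_corner_b: tuple
    settings: PipelineSettings = PipelineSettings()
    seed: int = 0
    output_dir: str = "out"

    def to_dict(self) -> dict:
        return {
            "transect_id": self.transect_id,
            "scan_logs": dict(self.scan_logs),
            "correspondences": dict(self.correspondences),
            "roi": {"corner_a": list(self.roi_corner_a),
                    "corner_b": list(self.roi_corner_b)},
            "settings": _settings_dict(self.settings),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _ALLOWED_TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for req in ("scan_logs", "correspondences", "roi"):
        if req not in raw:
            raise ValueError(f"missing required configuration key: {req!r}")
    for block_name in ("scan_logs", "correspondences"):
        block = raw[block_name]
        missing = set(_LOG_KEYS) - set(block)
        if missing:
            raise ValueError(f"{block_name} missing entries: {sorted(missing)}")
        extra = set(block) - set(_LOG_KEYS)
        if extra:
            raise ValueError(f"{block_name} has unknown entries: {sorted(extra)}")
    roi_block = raw["roi"]
    if set(roi_block) != {"corner_a", "corner_b"}:
        raise ValueError("roi block must contain exactly corner_a and corner_b")
    settings_raw = raw.get("settings", {})
    allowed_settings = set(PipelineSettings.__dataclass_fields__)
    unknown_settings = set(settings_raw) - allowed_settings
    if unknown_settings:
        raise ValueError(f"unknown settings keys: {sorted(unknown_settings)}")
    settings = PipelineSettings(**settings_raw)
    return RunConfig(
        transect_id=str(raw.get("transect_id", "transect")),
        scan_logs=dict(raw["scan_logs"]),
        correspondences=dict(raw["correspondences"]),
        roi_corner_a=tuple(roi_block["corner_a"]),
        roi_corner_b=tuple(roi_block["corner_b"]),
        settings=settings,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "out")),
    )


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _parse_key(key: str) -> tuple[int, str, str]:
    sensor_part, side, phase = key.split("_")
    return int(sensor_part.removeprefix("sensor")), side, phase


def run_from_config(config: RunConfig, write: bool = True) -> dict:
    """Execute the pipeline from a run configuration; optionally write the report."""
    sweeps = {}
    corrs = {}
    base = Path(".")
    for key in _LOG_KEYS:
        k = _parse_key(key)
        sweeps[k] = osio.read_sweep_log(base / config.scan_logs[key])
        src, dst, _ = osio.read_correspondences(base / config.correspondences[key])
        corrs[k] = (src, dst)
    poses = {(s, side): table_pose(s, side, config.settings.mount_height)
             for s in SENSORS for side in SIDES}
    result = run_transect(sweeps, poses, corrs,
                          np.asarray(config.roi_corner_a, float),
                          np.asarray(config.roi_corner_b, float),
                          config.settings, config.transect_id)
    report = report_to_dict(result)
    report["config"] = config.to_dict()
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        osio.write_report(report, out / f"{config.transect_id}_report.json")
    return report
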