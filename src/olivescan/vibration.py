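"""Tri-axial accelerometer analysis: beating-event detection and summaries.

Loggers strapped to the trees record x/y/z acceleration in raw counts
(2048 counts/g, +/-16 g, 100 Hz).  Because the devices sit at arbitrary
orientations on different branches, the per-sample Euclidean norm of the
axis triple is used as the working series — it is invariant to the device's
orientation, so trees can be compared directly.  The beating event is the
supra-threshold span of that magnitude series; its maximum and duration are
the per-tree damage indicators, averaged per harvesting treatment
(travel speed x beating frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COUNTS_PER_G = 2048
DEFAULT_THRESHOLD = 2.0  # g: above the 1 g gravity baseline, below beating peaks
DEFAULT_MIN_GAP = 0.5    # s: sub-threshold dips shorter than this stay in-event

__all__ = [
    "VibrationEvent",
    "VibrationSummary",
    "read_accel_log",
    "magnitude_series",
    "windowed_rms",
    "detect_events",
    "detect_event",
    "summarize_log",
    "treatment_summary",
    "percent_change",
    "COUNTS_PER_G",
]


@dataclass(frozen=True)
class VibrationEvent:
    """One supra-threshold vibration span."""

    t_start: float
    t_end: float
    duration: float
    max_value: float

    @property
    def empty(self) -> bool:
        return self.duration == 0.0 and np.isnan(self.max_value)

    @staticmethod
    def none() -> "VibrationEvent":
        return VibrationEvent(np.nan, np.nan, 0.0, np.nan)


@dataclass(frozen=True)
class VibrationSummary:
    """Per-tree vibration metrics under one harvesting treatment."""

    tree_id: str
    treatment: str
    max_rms_acc: float
    vibration_time: float


def read_accel_log(path) -> pd.DataFrame:
    """Read a logger CSV (time_s, x_counts, y_counts, z_counts) into g units.

    Returns a DataFrame with columns ``time_s, ax, ay, az`` (g).
    """
    df = pd.read_csv(path)
    required = {"time_s", "x_counts", "y_counts", "z_counts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"accelerometer log missing columns: {sorted(missing)}")
    return pd.DataFrame({
        "time_s": df["time_s"].astype(float),
        "ax": df["x_counts"] / COUNTS_PER_G,
        "ay": df["y_counts"] / COUNTS_PER_G,
        "az": df["z_counts"] / COUNTS_PER_G,
    })


def _axes(samples) -> np.ndarray:
    if isinstance(samples, pd.DataFrame):
        return samples[["ax", "ay", "az"]].to_numpy(dtype=float)
    return np.asarray(samples, dtype=float).reshape(-1, 3)


def magnitude_series(samples) -> np.ndarray:
    """Per-sample Euclidean norm of the axis triple (g).

    Orientation-invariant by construction: any rotation of the device leaves
    the series unchanged, so differently mounted loggers are comparable.
    Gravity is not subtracted — the series rests at ~1 g.
    """
    a = _axes(samples)
    return np.sqrt(np.sum(a * a, axis=1))


def windowed_rms(samples, window_s: float, sample_rate: float = 100.0) -> np.ndarray:
    """Moving root-mean-square of the magnitude series (sensitivity variant).

    Provided for sensitivity analysis next to the per-sample norm; a
    centred boxcar of ``window_s`` seconds is used.
    """
    m = magnitude_series(samples)
    w = max(int(round(window_s * sample_rate)), 1)
    kernel = np.ones(w) / w
    padded = np.pad(m * m, (w // 2, w - 1 - w // 2), mode="edge")
    return np.sqrt(np.convolve(padded, kernel, mode="valid"))


def detect_events(time_s: np.ndarray, magnitude: np.ndarray,
                  threshold: float = DEFAULT_THRESHOLD,
                  min_gap: float = DEFAULT_MIN_GAP) -> list[VibrationEvent]:
    """All supra-threshold events, sub-gaps shorter than ``min_gap`` merged.

    An event runs from its first to its last sample with magnitude >=
    threshold; dips below threshold shorter than ``min_gap`` do not split an
    event.  Events are returned in time order.
    """
    t = np.asarray(time_s, dtype=float)
    m = np.asarray(magnitude, dtype=float)
    if t.shape != m.shape:
        raise ValueError("time and magnitude must have the same length")
    above = np.nonzero(m >= threshold)[0]
    if len(above) == 0:
        return []
    breaks = np.nonzero(t[above][1:] - t[above][:-1] >= min_gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(above) - 1]])
    events = []
    for s, e in zip(starts, ends):
        i0, i1 = above[s], above[e]
        events.append(VibrationEvent(
            t_start=float(t[i0]), t_end=float(t[i1]),
            duration=float(t[i1] - t[i0]),
            max_value=float(m[i0:i1 + 1].max())))
    return events


def detect_event(time_s: np.ndarray, magnitude: np.ndarray,
                 threshold: float = DEFAULT_THRESHOLD,
                 min_gap: float = DEFAULT_MIN_GAP) -> VibrationEvent:
    """First supra-threshold event, or an empty event if none occurs."""
    events = detect_events(time_s, magnitude, threshold, min_gap)
    return events[0] if events else VibrationEvent.none()


def summarize_log(log: pd.DataFrame, tree_id: str, treatment: str,
                  threshold: float = DEFAULT_THRESHOLD,
                  min_gap: float = DEFAULT_MIN_GAP,
                  remove_baseline: bool = False) -> VibrationSummary:
    """Per-tree summary (max magnitude, vibration time) from one log.

    With ``remove_baseline`` the pre-event median magnitude (gravity and
    idling) is subtracted before detection.
    """
    m = magnitude_series(log)
    t = log["time_s"].to_numpy(dtype=float)
    if remove_baseline:
        first_above = np.argmax(m >= threshold) if np.any(m >= threshold) else len(m)
        baseline = float(np.median(m[:first_above])) if first_above > 0 else 0.0
        m = m - baseline
    ev = detect_event(t, m, threshold, min_gap)
    return VibrationSummary(tree_id=tree_id, treatment=treatment,
                            max_rms_acc=ev.max_value if not ev.empty else float(np.max(m)),
                            vibration_time=ev.duration)


def treatment_summary(per_tree: list[VibrationSummary] | pd.DataFrame) -> pd.DataFrame:
    """Arithmetic means of per-tree maxima and durations per treatment."""
    if isinstance(per_tree, pd.DataFrame):
        df = per_tree
    else:
        if not per_tree:
            raise ValueError("no per-tree summaries provided")
        df = pd.DataFrame([{
            "treatment": s.treatment, "tree_id": s.tree_id,
            "max_rms_acc": s.max_rms_acc, "vibration_time": s.vibration_time,
        } for s in per_tree])
    if df.empty:
        raise ValueError("no per-tree summaries provided")
    out = (df.groupby("treatment", sort=False)
             .agg(mean_max_acc=("max_rms_acc", "mean"),
                  mean_vibration_time=("vibration_time", "mean"),
                  n_trees=("tree_id", "count"))
             .reset_index())
    return out


def percent_change(value_a: float, value_b: float) -> float:
    """Percent change of A relative to B: (A - B) / B * 100."""
    if value_b == 0:
        raise ValueError("reference value is zero")
    return (value_a - value_b) / value_b * 100.0
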