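"""File formats: PLY/XYZ point clouds, sweep-log CSV, correspondences, reports.

The canonical cloud format is PLY (binary little-endian by default, ASCII on
request); whitespace-delimited XYZ is accepted for interoperability.  Sweep
logs use one CSV row per scanner revolution: ``timestamp_s, encoder_count,
r_000 ... r_270`` with ranges in metres at 3 decimals — the same dialect the
simulator writes and the cloud builder reads.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import N_BEAMS, PointCloud, SweepRecord

REPORT_SCHEMA_VERSION = 1

__all__ = [
    "write_ply", "read_ply", "write_xyz", "read_xyz",
    "write_sweep_log", "read_sweep_log",
    "write_correspondences", "read_correspondences",
    "write_report", "read_report", "REPORT_SCHEMA_VERSION",
]


def write_ply(path, cloud: PointCloud | np.ndarray, binary: bool = True) -> None:
    """Write a point cloud as PLY (binary little-endian or ASCII)."""
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float).reshape(-1, 3)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {len(pts)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "end_header\n"
    )
    path = Path(path)
    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(np.ascontiguousarray(pts, dtype="<f8").tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, pts, fmt="%.6f")


_PLY_DTYPES = {"float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
               "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
               "short": "<i2", "ushort": "<u2", "int": "<i4", "int32": "<i4",
               "uint": "<u4", "uint32": "<u4"}


def read_ply(path) -> PointCloud:
    """Read a PLY point cloud (vertex x/y/z; ASCII or binary little-endian)."""
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValueError("list properties unsupported in vertex element")
                props.append((tokens[2], _PLY_DTYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt is None or n_vertex is None:
            raise ValueError(f"{path}: malformed PLY header")
        names = [p[0] for p in props]
        if not {"x", "y", "z"} <= set(names):
            raise ValueError(f"{path}: PLY vertex element lacks x/y/z")
        if fmt == "ascii":
            data = np.loadtxt(fh, max_rows=n_vertex).reshape(n_vertex, len(props))
            rec = {n: data[:, i] for i, (n, _) in enumerate(props)}
        elif fmt == "binary_little_endian":
            dtype = np.dtype([(n, d) for n, d in props])
            raw = fh.read(dtype.itemsize * n_vertex)
            arr = np.frombuffer(raw, dtype=dtype, count=n_vertex)
            rec = {n: arr[n] for n, _ in props}
        else:
            raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
    pts = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(float)
    return PointCloud(pts)


def write_xyz(path, cloud: PointCloud | np.ndarray) -> None:
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float).reshape(-1, 3)
    np.savetxt(path, pts, fmt="%.6f")


def read_xyz(path) -> PointCloud:
    pts = np.loadtxt(path, dtype=float)
    return PointCloud(np.atleast_2d(pts)[:, :3])


def _range_columns() -> list[str]:
    return [f"r_{i:03d}" for i in range(N_BEAMS)]


def write_sweep_log(path, sweeps: list[SweepRecord]) -> None:
    """Write sweeps as the canonical CSV dialect (ranges at 3 decimals)."""
    cols = _range_columns()
    df = pd.DataFrame([np.round(s.ranges, 3) for s in sweeps], columns=cols)
    df.insert(0, "encoder_count", [s.encoder_count for s in sweeps])
    df.insert(0, "timestamp_s", [s.timestamp for s in sweeps])
    df.to_csv(path, index=False, float_format="%.3f")


def read_sweep_log(path) -> list[SweepRecord]:
    df = pd.read_csv(path)
    cols = _range_columns()
    missing = set(["timestamp_s", "encoder_count"] + cols) - set(df.columns)
    if missing:
        raise ValueError(f"sweep log missing columns, e.g. {sorted(missing)[:3]}")
    ranges = df[cols].to_numpy(dtype=float)
    return [SweepRecord(timestamp=float(t), encoder_count=int(e), ranges=r)
            for t, e, r in zip(df["timestamp_s"], df["encoder_count"], ranges)]


def write_correspondences(path, src: np.ndarray, dst: np.ndarray,
                          names: list[str] | None = None) -> None:
    src = np.asarray(src, float).reshape(-1, 3)
    dst = np.asarray(dst, float).reshape(-1, 3)
    if names is None:
        names = [f"p{i}" for i in range(len(src))]
    df = pd.DataFrame({
        "point_name": names,
        "src_x": src[:, 0], "src_y": src[:, 1], "src_z": src[:, 2],
        "dst_x": dst[:, 0], "dst_y": dst[:, 1], "dst_z": dst[:, 2],
    })
    df.to_csv(path, index=False)


def read_correspondences(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path)
    cols = ["src_x", "src_y", "src_z", "dst_x", "dst_y", "dst_z"]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"correspondence file missing columns: {sorted(missing)}")
    src = df[cols[:3]].to_numpy(dtype=float)
    dst = df[cols[3:]].to_numpy(dtype=float)
    names = (df["point_name"].astype(str).tolist()
             if "point_name" in df.columns else [f"p{i}" for i in range(len(df))])
    return src, dst, names


def write_report(report: dict, path) -> None:
    """Serialise a pipeline report as versioned JSON."""
    out = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    if "schema_version" not in report:
        raise ValueError(f"{path}: report lacks schema_version")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
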