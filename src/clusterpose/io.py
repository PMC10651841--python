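"""Marker-trajectory and pose-series file I/O.

Supports the tab-delimited TRC format used by motion-capture pipelines
(header rows with DataRate / NumFrames / Units, then X/Y/Z columns per
marker) and a long-format CSV fallback with columns
``time, marker, x, y, z``.  Pose series are exported as CSV with a
quaternion + translation per row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import InvalidInputError, MarkerTrajectorySet

__all__ = [
    "read_trc",
    "write_trc",
    "read_csv_trajectories",
    "write_csv_trajectories",
    "write_pose_csv",
    "read_pose_csv",
]


def write_trc(path: str | Path, traj: MarkerTrajectorySet, units: str = "m") -> None:
    """Write a trajectory set to a TRC file."""
    path = Path(path)
    n_t, n = traj.n_samples, traj.n_markers
    rate = traj.sample_rate
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:g}\t{rate:g}\t{n_t}\t{n}\t{units}\t{rate:g}\t1\t{n_t}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(traj.labels) + "\t\t\t\n")
        sub = "\t".join(f"X{j+1}\tY{j+1}\tZ{j+1}" for j in range(n))
        fh.write(f"\t\t{sub}\n\n")
        for i in range(n_t):
            row = [str(i + 1), f"{traj.times[i]:.8f}"]
            row += [f"{c:.10f}" for c in traj.positions[i].ravel()]
            fh.write("\t".join(row) + "\n")


def read_trc(path: str | Path) -> MarkerTrajectorySet:
    """Read a TRC file into a :class:`MarkerTrajectorySet`."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise InvalidInputError(f"{path}: not a TRC file (too short)")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    rate = float(meta.get("DataRate", 0))
    n = int(meta.get("NumMarkers", 0))
    units = meta.get("Units", "m")
    labels = [s for s in lines[3].split("\t")[2:] if s.strip()]
    if len(labels) != n:
        raise InvalidInputError(f"{path}: NumMarkers={n} but found {len(labels)} labels")
    scale = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}.get(units.lower(), 1.0)
    times, frames = [], []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        times.append(float(parts[1]))
        vals = np.array([float(v) for v in parts[2 : 2 + 3 * n]])
        frames.append(vals.reshape(n, 3) * scale)
    return MarkerTrajectorySet(labels, np.array(times), np.array(frames), rate)


def write_csv_trajectories(path: str | Path, traj: MarkerTrajectorySet) -> None:
    """Long-format CSV fallback: columns time, marker, x, y, z (metres)."""
    rows = []
    for i, t in enumerate(traj.times):
        for j, lab in enumerate(traj.labels):
            x, y, z = traj.positions[i, j]
            rows.append((t, lab, x, y, z))
    pd.DataFrame(rows, columns=["time", "marker", "x", "y", "z"]).to_csv(path, index=False)


def read_csv_trajectories(path: str | Path, sample_rate: float | None = None) -> MarkerTrajectorySet:
    df = pd.read_csv(path)
    required = {"time", "marker", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"{path}: CSV must have columns {sorted(required)}")
    labels = list(dict.fromkeys(df["marker"]))
    times = np.sort(df["time"].unique())
    pos = np.full((times.size, len(labels), 3), np.nan)
    t_index = {t: i for i, t in enumerate(times)}
    l_index = {lab: j for j, lab in enumerate(labels)}
    for row in df.itertuples(index=False):
        pos[t_index[row.time], l_index[row.marker]] = (row.x, row.y, row.z)
    if sample_rate is None:
        dt = np.diff(times)
        sample_rate = 1.0 / float(np.median(dt)) if dt.size else 1.0
    return MarkerTrajectorySet(labels, times, pos, sample_rate)


def write_pose_csv(path: str | Path, times: np.ndarray, rotations: np.ndarray,
                   translations: np.ndarray, method: str = "") -> None:
    """Export a pose series as CSV: time, unit quaternion (x,y,z,w), translation."""
    quat = Rotation.from_matrix(np.asarray(rotations)).as_quat()
    df = pd.DataFrame(
        {
            "time": np.asarray(times),
            "qx": quat[:, 0], "qy": quat[:, 1], "qz": quat[:, 2], "qw": quat[:, 3],
            "tx": translations[:, 0], "ty": translations[:, 1], "tz": translations[:, 2],
        }
    )
    if method:
        df.insert(0, "method", method)
    df.to_csv(path, index=False)


def read_pose_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a pose CSV; returns (times, rotations (N,3,3), translations (N,3))."""
    df = pd.read_csv(path)
    quat = df[["qx", "qy", "qz", "qw"]].to_numpy()
    rot = Rotation.from_quat(quat).as_matrix()
    return df["time"].to_numpy(), rot, df[["tx", "ty", "tz"]].to_numpy()
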