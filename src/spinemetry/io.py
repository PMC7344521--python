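"""Delimited-text persistence for datasets, ROM tables and scores.

All files are UTF-8 comma-separated with a header row and '.' decimal
separator; times are written to 6 decimals.  Sensor and marker identifiers
encode their provenance as ``subject:plane:region:role`` /
``subject:region:plane:marker`` so a whole cohort round-trips through the
flat schema.  On read, sample times are snapped back onto the exact uniform
grid implied by the inferred rate (undoing the 1 µs write rounding) whenever
they are within a hundredth of a sample step of it.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .series import MarkerTrajectory, OrientationSeries, Plane, Region
from .motion_sim import Dataset

__all__ = ["write_dataset", "read_dataset"]

_ORIENT_COLS = ["time_s", "sensor_id", "roll_deg", "pitch_deg", "yaw_deg"]
_MARKER_COLS = ["time_s", "marker_id", "x_mm", "y_mm", "z_mm"]


def _snap_times(t: np.ndarray) -> tuple[np.ndarray, float]:
    """Reconstruct the exact uniform grid from written (rounded) times."""
    if t.size < 2:
        return t, 1.0
    dt = float(np.median(np.diff(t)))
    rate = 1.0 / dt
    # prefer an integer rate when the data are consistent with one
    if abs(rate - round(rate)) < 0.01 * rate:
        rate = float(round(rate))
    grid = t[0] + np.arange(t.size) / rate
    if np.max(np.abs(grid - t)) < 0.01 / rate:
        return grid, rate
    return t, rate


def write_dataset(ds: Dataset, out_dir: str | Path) -> Path:
    """Write a dataset directory (subjects/truth/orientation/markers/outcomes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.subjects.to_csv(out / "subjects.csv", index=False)
    if ds.truth is not None:
        ds.truth.to_csv(out / "truth.csv", index=False, float_format="%.6f")
    if ds.outcomes is not None:
        ds.outcomes.to_csv(out / "outcomes.csv", index=False, float_format="%.6f")

    frames = []
    for (_sid, _region, _plane), (upper, lower) in sorted(ds.imu.items()):
        for s in (upper, lower):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": np.round(s.t, 6),
                        "sensor_id": s.sensor_id,
                        "roll_deg": s.roll,
                        "pitch_deg": s.pitch,
                        "yaw_deg": s.yaw,
                    }
                )
            )
    orient = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_ORIENT_COLS)
    orient.to_csv(out / "orientation.csv", index=False, float_format="%.6f")

    frames = []
    for (_sid, _region, _plane), (a, b) in sorted(ds.mocap.items()):
        for m in (a, b):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": np.round(m.t, 6),
                        "marker_id": m.marker_id,
                        "x_mm": m.xyz[:, 0],
                        "y_mm": m.xyz[:, 1],
                        "z_mm": m.xyz[:, 2],
                    }
                )
            )
    markers = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_MARKER_COLS)
    markers.to_csv(out / "markers.csv", index=False, float_format="%.6f")

    meta = {"protocol": ds.protocol, "provenance": ds.provenance}
    (out / "provenance.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def read_dataset(data_dir: str | Path) -> Dataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    root = Path(data_dir)
    if not (root / "subjects.csv").exists():
        raise DataError(f"no subjects.csv under {root}")
    subjects = pd.read_csv(root / "subjects.csv")
    truth = pd.read_csv(root / "truth.csv") if (root / "truth.csv").exists() else None
    outcomes = pd.read_csv(root / "outcomes.csv") if (root / "outcomes.csv").exists() else None
    protocol, provenance = {}, {}
    if (root / "provenance.json").exists():
        meta = json.loads((root / "provenance.json").read_text())
        protocol = meta.get("protocol", {})
        provenance = meta.get("provenance", {})

    imu: dict = {}
    if (root / "orientation.csv").exists():
        orient = pd.read_csv(root / "orientation.csv")
        pending: dict = {}
        for sensor_id, g in orient.groupby("sensor_id", sort=True):
            try:
                sid, plane_s, region_s, role = sensor_id.split(":")
            except ValueError as exc:
                raise DataError(f"malformed sensor_id {sensor_id!r}") from exc
            t, rate = _snap_times(g["time_s"].to_numpy())
            series = OrientationSeries(
                sensor_id, rate, t,
                g["roll_deg"].to_numpy(), g["pitch_deg"].to_numpy(), g["yaw_deg"].to_numpy(),
            )
            pending.setdefault((sid, Region(region_s), Plane(plane_s)), {})[role] = series
        for key, roles in pending.items():
            if set(roles) != {"upper", "lower"}:
                raise DataError(f"recording {key} is missing a sensor role")
            imu[key] = (roles["upper"], roles["lower"])

    mocap: dict = {}
    if (root / "markers.csv").exists():
        markers = pd.read_csv(root / "markers.csv")
        pending = {}
        for marker_id, g in markers.groupby("marker_id", sort=True):
            try:
                sid, region_s, plane_s, which = marker_id.split(":")
            except ValueError as exc:
                raise DataError(f"malformed marker_id {marker_id!r}") from exc
            t, _rate = _snap_times(g["time_s"].to_numpy())
            traj = MarkerTrajectory(
                marker_id, t, g[["x_mm", "y_mm", "z_mm"]].to_numpy()
            )
            pending.setdefault((sid, Region(region_s), Plane(plane_s)), {})[which] = traj
        for key, pair in pending.items():
            if set(pair) != {"a", "b"}:
                raise DataError(f"marker pair {key} is incomplete")
            mocap[key] = (pair["a"], pair["b"])

    return Dataset(
        subjects=subjects,
        imu=imu,
        mocap=mocap,
        truth=truth,
        outcomes=outcomes,
        protocol=protocol,
        provenance=provenance,
    )
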