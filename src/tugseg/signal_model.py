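"""Core data model: IMU recordings, orientation conversion, report I/O.

A recording is the uniformly sampled multi-channel time series delivered by a
single lumbar-mounted IMU whose onboard fusion already provides orientation.
Only the channels the segmentation needs are mandatory: time plus either
Euler pitch/yaw (degrees) or a unit quaternion, from which pitch/yaw are
derived.  Inertial channels (3-axis acceleration in m/s^2, 3-axis angular
velocity in deg/s) are optional and used for the per-sub-task features.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .config import AlgorithmConfig, DEFAULT_CONFIG
from .errors import DataError, SchemaError

__all__ = [
    "ImuRecording",
    "read_recording",
    "quaternion_to_euler",
    "euler_to_quaternion",
    "write_report",
    "read_report",
    "DEFAULT_COLUMNS",
]

#: Default column names accepted by :func:`read_recording`.
DEFAULT_COLUMNS = {
    "time": "time",
    "pitch": "pitch_deg",
    "yaw": "yaw_deg",
    "roll": "roll_deg",
    "qw": "qw",
    "qx": "qx",
    "qy": "qy",
    "qz": "qz",
    "acc_x": "acc_x",
    "acc_y": "acc_y",
    "acc_z": "acc_z",
    "gyr_x": "gyr_x",
    "gyr_y": "gyr_y",
    "gyr_z": "gyr_z",
}


@dataclass
class ImuRecording:
    """Uniformly sampled orientation + inertial time series.

    ``t`` is seconds from the start of the recording, ``fs`` the sampling
    rate in Hz.  ``pitch`` is the sagittal trunk inclination (forward lean
    positive) and ``yaw`` the transverse-plane heading, both in degrees.
    ``acc_z`` is the vertical/longitudinal acceleration channel used for
    step detection; ``gyr_z`` the transverse (turning) angular rate.
    """

    t: np.ndarray
    fs: float
    pitch: np.ndarray
    yaw: np.ndarray
    roll: np.ndarray | None = None
    acc_x: np.ndarray | None = None
    acc_y: np.ndarray | None = None
    acc_z: np.ndarray | None = None
    gyr_x: np.ndarray | None = None
    gyr_y: np.ndarray | None = None
    gyr_z: np.ndarray | None = None
    subject_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        for name in ("roll", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        self.validate()

    def validate(self) -> None:
        n = self.t.size
        if n < 2:
            raise DataError("recording must contain at least 2 samples")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        for name in ("pitch", "yaw", "roll", "acc_x", "acc_y", "acc_z",
                     "gyr_x", "gyr_y", "gyr_z"):
            v = getattr(self, name)
            if v is not None and v.size != n:
                raise DataError(f"channel {name!r} length {v.size} != time length {n}")
        if not np.all(np.diff(self.t) > 0):
            raise DataError("time vector must be strictly increasing")
        dt = 1.0 / self.fs
        if np.max(np.abs(np.diff(self.t) - dt)) > 0.25 * dt:
            raise DataError("time vector is not uniform at the stated sampling rate")
        if not (np.all(np.isfinite(self.pitch)) and np.all(np.isfinite(self.yaw))):
            raise DataError("pitch/yaw contain non-finite values")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    def index_at(self, time_s: float) -> int:
        """Index of the sample nearest to ``time_s`` (seconds)."""
        i = int(round((time_s - self.t[0]) * self.fs))
        return min(max(i, 0), self.n_samples - 1)


def quaternion_to_euler(
    w: float | np.ndarray,
    x: float | np.ndarray,
    y: float | np.ndarray,
    z: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert unit quaternion(s) to intrinsic Z-Y-X Euler angles in degrees.

    Returns ``(yaw, pitch, roll)`` with yaw in (-180, 180] and pitch in
    [-90, 90].  Inputs are normalized first; a (near-)zero-norm quaternion
    raises ``ValueError``.
    """
    q = np.stack(np.broadcast_arrays(
        np.asarray(x, float), np.asarray(y, float),
        np.asarray(z, float), np.asarray(w, float)), axis=-1)
    norm = np.linalg.norm(q, axis=-1)
    if np.any(norm < 1e-12):
        raise ValueError("zero-norm quaternion cannot encode an orientation")
    rot = Rotation.from_quat(q / norm[..., None])
    ang = rot.as_euler("ZYX", degrees=True)
    ang = np.atleast_2d(ang)
    yaw, pitch, roll = ang[..., 0], ang[..., 1], ang[..., 2]
    if np.isscalar(w) or np.asarray(w).ndim == 0:
        return float(yaw[0]), float(pitch[0]), float(roll[0])
    return yaw, pitch, roll


def euler_to_quaternion(yaw: float, pitch: float, roll: float) -> tuple[float, float, float, float]:
    """Inverse of :func:`quaternion_to_euler`; returns ``(w, x, y, z)``."""
    q = Rotation.from_euler("ZYX", [yaw, pitch, roll], degrees=True).as_quat()
    return float(q[3]), float(q[0]), float(q[1]), float(q[2])


def _resample(t: np.ndarray, values: Mapping[str, np.ndarray], fs: float
              ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Linear resampling of all channels onto a uniform grid at ``fs``."""
    dt = 1.0 / fs
    span = t[-1] - t[0]
    n = int(round(span * fs)) + 1
    grid = t[0] + np.arange(n) * dt
    # Identity case: grid already matches the source within a small fraction
    # of a sample period — keep the original samples untouched.
    if t.size == n and np.max(np.abs(t - grid)) <= 0.01 * dt:
        return t.copy(), {k: np.asarray(v, float).copy() for k, v in values.items()}
    out = {k: np.interp(grid, t, np.asarray(v, float)) for k, v in values.items()}
    return grid, out


def read_recording(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> ImuRecording:
    """Read a delimited-text IMU recording and resample it to ``target_fs``.

    The file must have a header row.  ``column_map`` maps the logical names
    in :data:`DEFAULT_COLUMNS` to the file's column names; unmapped logical
    names fall back to the defaults.  Orientation may be given either as
    Euler columns (pitch/yaw, degrees) or as quaternion columns (qw..qz),
    which are converted.  The delimiter is sniffed (comma, tab, semicolon,
    whitespace).
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed text
        raise SchemaError(f"could not parse {path!r} as delimited text: {exc}") from exc

    def has(key: str) -> bool:
        return cols[key] in df.columns

    if not has("time"):
        raise SchemaError(f"missing required time column {cols['time']!r}")
    t = df[cols["time"]].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError("recording must contain at least 2 samples")
    if not np.all(np.diff(t) > 0):
        raise DataError("time column must be strictly increasing")

    channels: dict[str, np.ndarray] = {}
    have_euler = has("pitch") and has("yaw")
    have_quat = all(has(k) for k in ("qw", "qx", "qy", "qz"))
    if have_euler:
        channels["pitch"] = df[cols["pitch"]].to_numpy(float)
        channels["yaw"] = df[cols["yaw"]].to_numpy(float)
        if has("roll"):
            channels["roll"] = df[cols["roll"]].to_numpy(float)
    elif have_quat:
        yaw, pitch, roll = quaternion_to_euler(
            df[cols["qw"]].to_numpy(float), df[cols["qx"]].to_numpy(float),
            df[cols["qy"]].to_numpy(float), df[cols["qz"]].to_numpy(float))
        channels["pitch"], channels["yaw"], channels["roll"] = pitch, yaw, roll
    else:
        raise SchemaError(
            f"missing orientation columns: need ({cols['pitch']!r}, {cols['yaw']!r}) "
            f"or ({cols['qw']!r}..{cols['qz']!r})")

    for key in ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"):
        if has(key):
            channels[key] = df[cols[key]].to_numpy(float)

    for name, v in channels.items():
        if not np.all(np.isfinite(v)) and name in ("pitch", "yaw"):
            raise DataError(f"channel {name!r} contains non-finite values")

    grid, resampled = _resample(t, channels, config.target_fs)
    grid = grid - grid[0]
    return ImuRecording(
        t=grid,
        fs=config.target_fs,
        pitch=resampled["pitch"] * (-1.0 if config.invert_pitch else 1.0),
        yaw=resampled["yaw"] * (-1.0 if config.invert_yaw else 1.0),
        roll=resampled.get("roll"),
        acc_x=resampled.get("acc_x"),
        acc_y=resampled.get("acc_y"),
        acc_z=resampled.get("acc_z"),
        gyr_x=resampled.get("gyr_x"),
        gyr_y=resampled.get("gyr_y"),
        gyr_z=resampled.get("gyr_z"),
    )


def write_recording(recording: ImuRecording, path: str | os.PathLike) -> None:
    """Write a recording as CSV in the schema :func:`read_recording` accepts."""
    data = {"time": recording.t, "pitch_deg": recording.pitch, "yaw_deg": recording.yaw}
    optional = {"roll_deg": recording.roll, "acc_x": recording.acc_x,
                "acc_y": recording.acc_y, "acc_z": recording.acc_z,
                "gyr_x": recording.gyr_x, "gyr_y": recording.gyr_y,
                "gyr_z": recording.gyr_z}
    for k, v in optional.items():
        if v is not None:
            data[k] = v
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


REPORT_SCHEMA_VERSION = "1.0"


def _round_times(obj: Any) -> Any:
    if isinstance(obj, float):
        return round(obj, 3)
    if isinstance(obj, dict):
        return {k: _round_times(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_times(v) for v in obj]
    return obj


def write_report(segmentation, features, risk, path: str | os.PathLike,
                 config: AlgorithmConfig = DEFAULT_CONFIG) -> dict[str, Any]:
    """Write the JSON analysis report; returns the report dict.

    Event times and durations are reported in seconds at 3 decimals (times
    are sample-aligned at 100 Hz, so rounding is exact); the resolved
    configuration is embedded for reproducibility.
    """
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "segmentation": _round_times(segmentation.to_dict()),
        "features": _round_times(features.to_dict()),
        "risk": _round_times(risk.to_dict()),
        "config": config.to_dict(),
    }
    directory = os.path.dirname(os.fspath(path))
    if directory and not os.path.isdir(directory):
        raise IOError(f"report directory does not exist: {directory!r}")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def read_report(path: str | os.PathLike) -> dict[str, Any]:
    """Read back a report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
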