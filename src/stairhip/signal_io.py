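"""Sensor-stream containers, delimited-text I/O and pre-processing.

File schemas (comma separated, one header row, SI units):

* IMU:    ``t, acc_x, acc_y, acc_z, gyr_x, gyr_y, gyr_z, mag_x, mag_y, mag_z,
          quat_w, quat_x, quat_y, quat_z``
  Sensor axes: x anterior, y longitudinal (proximal, "up" along the segment),
  z lateral.  Quaternions are scalar-first Hamilton convention and map sensor
  frame to lab frame.
* Insole: ``t, grf_v``  (vertical ground reaction force, N)
* Marker: ``t, pos_x, pos_y, pos_z``  (lab frame: x anteroposterior,
  y vertical, z mediolateral, metres)

Pre-processing mirrors the wearable workflow: zero-phase low-pass Butterworth
filtering (10 Hz for insole/IMU channels, 6 Hz for markers, 2.3 Hz for the
shank gyro used in event detection), linear resampling of the 100 Hz insole
onto the 128 Hz IMU clock, and rotation of the shank IMU about its
longitudinal axis from its as-worn anteromedial mounting to a pure lateral
orientation (goniometrically measured angle, cohort mean 121.3 deg).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.transform import Rotation

__all__ = [
    "ImuStream", "InsoleStream", "MarkerTrace", "FilterSpec",
    "SchemaError", "FormatError",
    "read_stream", "write_stream", "lowpass", "resample_to",
    "rotate_shank_imu", "longitudinal_rotation_matrix",
    "SHANK_MOUNT_ANGLE_DEG",
]

#: goniometrically captured rotation from as-worn shank IMU orientation to
#: pure lateral (cohort mean)
SHANK_MOUNT_ANGLE_DEG = 121.3

IMU_COLUMNS = ["t", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z",
               "mag_x", "mag_y", "mag_z", "quat_w", "quat_x", "quat_y", "quat_z"]
INSOLE_COLUMNS = ["t", "grf_v"]
MARKER_COLUMNS = ["t", "pos_x", "pos_y", "pos_z"]

_MAX_NAN_GAP_S = 0.1
_MAX_JITTER_FRAC = 0.01


class SchemaError(ValueError):
    """File columns do not match the requested schema."""


class FormatError(ValueError):
    """File contents violate the stream contract (timing, gaps)."""


def _check_time(t, where):
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise FormatError(f"{where}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{where}: time must be strictly increasing")
    step = np.median(dt)
    if np.max(np.abs(dt - step)) > _MAX_JITTER_FRAC * step:
        raise FormatError(f"{where}: non-uniform timestamps beyond 1% jitter")
    return t, 1.0 / step


@dataclass
class ImuStream:
    """13-channel inertial stream for one body-segment-mounted sensor."""

    segment_label: str
    fs: float
    t: np.ndarray
    acc: np.ndarray   # (3, N) m/s^2
    gyro: np.ndarray  # (3, N) rad/s
    mag: np.ndarray   # (3, N) a.u.
    quat: np.ndarray  # (4, N) scalar-first unit quaternions, sensor->lab

    def __post_init__(self):
        if self.segment_label not in ("shank", "thigh"):
            raise ValueError("segment_label must be 'shank' or 'thigh'")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.t, _ = _check_time(self.t, "ImuStream")
        n = self.t.size
        for name in ("acc", "gyro", "mag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (3, n):
                raise ValueError(f"{name} must have shape (3, {n})")
            setattr(self, name, arr)
        q = np.asarray(self.quat, dtype=float)
        if q.shape != (4, n):
            raise ValueError(f"quat must have shape (4, {n})")
        norms = np.linalg.norm(q, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternion columns must have unit norm (1e-6)")
        self.quat = q / norms

    @property
    def n_samples(self):
        return self.t.size

    def copy(self):
        return dataclasses.replace(
            self, t=self.t.copy(), acc=self.acc.copy(), gyro=self.gyro.copy(),
            mag=self.mag.copy(), quat=self.quat.copy())


@dataclass
class InsoleStream:
    """Vertical GRF time series for the dominant foot."""

    fs: float
    t: np.ndarray
    grf_v: np.ndarray  # (N,) N, clamped >= 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.t, _ = _check_time(self.t, "InsoleStream")
        g = np.asarray(self.grf_v, dtype=float)
        if g.shape != self.t.shape:
            raise ValueError("grf_v must match t in length")
        self.grf_v = np.clip(g, 0.0, None)

    @property
    def n_samples(self):
        return self.t.size

    def copy(self):
        return dataclasses.replace(self, t=self.t.copy(), grf_v=self.grf_v.copy())


@dataclass
class MarkerTrace:
    """3D trajectory of one optical marker in the lab frame."""

    name: str
    fs: float
    t: np.ndarray
    pos: np.ndarray  # (3, N) m

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.t, _ = _check_time(self.t, "MarkerTrace")
        p = np.asarray(self.pos, dtype=float)
        if p.shape != (3, self.t.size):
            raise ValueError(f"pos must have shape (3, {self.t.size})")
        if not np.all(np.isfinite(p)):
            raise ValueError("marker positions must be finite after gap filling")
        self.pos = p

    @property
    def n_samples(self):
        return self.t.size

    def copy(self):
        return dataclasses.replace(self, t=self.t.copy(), pos=self.pos.copy())


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification (applied forward-backward)."""

    cutoff_hz: float
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def _fill_gaps(df, fs, path):
    """Linear interpolation of NaN runs up to 0.1 s; longer runs are an error."""
    max_run = max(int(round(_MAX_NAN_GAP_S * fs)), 1)
    for col in df.columns:
        isnan = df[col].isna().to_numpy()
        if not isnan.any():
            continue
        run = 0
        for flag in isnan:
            run = run + 1 if flag else 0
            if run > max_run:
                raise FormatError(
                    f"{path}: NaN run longer than {_MAX_NAN_GAP_S} s in '{col}'")
        if isnan[0] or isnan[-1]:
            raise FormatError(f"{path}: NaN at stream boundary in '{col}'")
        df[col] = df[col].interpolate(method="linear")
    return df


def read_stream(path, schema, segment_label="shank", name="heel"):
    """Read a delimited-text sensor stream.

    Parameters
    ----------
    schema : {"imu", "insole", "marker"}
    segment_label : used for ``schema="imu"``
    name : used for ``schema="marker"``
    """
    expected = {"imu": IMU_COLUMNS, "insole": INSOLE_COLUMNS,
                "marker": MARKER_COLUMNS}.get(schema)
    if expected is None:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[expected].astype(float)
    if df["t"].isna().any():
        raise FormatError(f"{path}: NaN in time column")
    t, fs = _check_time(df["t"].to_numpy(), str(path))
    df = _fill_gaps(df, fs, path)
    if schema == "imu":
        return ImuStream(
            segment_label=segment_label, fs=fs, t=t,
            acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy().T,
            gyro=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy().T,
            mag=df[["mag_x", "mag_y", "mag_z"]].to_numpy().T,
            quat=df[["quat_w", "quat_x", "quat_y", "quat_z"]].to_numpy().T)
    if schema == "insole":
        return InsoleStream(fs=fs, t=t, grf_v=df["grf_v"].to_numpy())
    return MarkerTrace(name=name, fs=fs, t=t,
                       pos=df[["pos_x", "pos_y", "pos_z"]].to_numpy().T)


def write_stream(stream, path):
    """Write a stream back to its delimited-text schema (lossless to ~1e-12)."""
    if isinstance(stream, ImuStream):
        data = np.vstack([stream.t, stream.acc, stream.gyro, stream.mag,
                          stream.quat]).T
        cols = IMU_COLUMNS
    elif isinstance(stream, InsoleStream):
        data = np.vstack([stream.t, stream.grf_v]).T
        cols = INSOLE_COLUMNS
    elif isinstance(stream, MarkerTrace):
        data = np.vstack([stream.t, stream.pos]).T
        cols = MARKER_COLUMNS
    else:
        raise TypeError(f"cannot write {type(stream).__name__}")
    pd.DataFrame(data, columns=cols).to_csv(path, index=False,
                                            float_format="%.14g")


def lowpass(series, fs, spec):
    """Low-pass Butterworth filter of a 1D signal; output length == input."""
    series = np.asarray(series, dtype=float)
    if spec.cutoff_hz >= fs / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if series.size <= 3 * spec.order:
        raise ValueError("series too short for the requested filter order")
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs,
                     output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, series)
    return sps.sosfilt(sos, series)


def resample_to(series, fs_in, fs_out):
    """Linear resampling onto a uniform ``fs_out`` grid over the same span.

    Output length is ``floor((N - 1) * fs_out / fs_in) + 1``.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling frequencies must be positive")
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 2:
        raise ValueError("need at least two samples to resample")
    n_out = int(np.floor((n - 1) * fs_out / fs_in)) + 1
    t_in = np.arange(n) / fs_in
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, series)


def longitudinal_rotation_matrix(angle_deg):
    """Rotation about the sensor longitudinal (y) axis.

    Positive angles carry the anterior axis (x) toward lateral (+z):
    ``R @ [1,0,0] = [cos a, 0, sin a]``.
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def rotate_shank_imu(stream, angle_deg):
    """Re-express a shank IMU stream in a frame rotated about the segment
    longitudinal axis by ``angle_deg`` (vector channels ``v' = R v``;
    orientation quaternions composed consistently so that the implied lab-frame
    vectors are unchanged)."""
    if stream.segment_label != "shank":
        raise ValueError("rotate_shank_imu expects a shank stream")
    R = longitudinal_rotation_matrix(angle_deg)
    # channels transform as v_new = R v_old; the new sensor basis is therefore
    # S' with (S <- S') = R^T, so (lab <- S') = (lab <- S) o R^T
    q_old = Rotation.from_quat(stream.quat.T[:, [1, 2, 3, 0]])  # to scalar-last
    q_new = q_old * Rotation.from_matrix(R.T)
    quat = q_new.as_quat()[:, [3, 0, 1, 2]].T  # back to scalar-first
    # fix the sign convention (scipy may flip quaternion sign)
    quat *= np.where(quat[0] < 0, -1.0, 1.0)
    return ImuStream(
        segment_label=stream.segment_label, fs=stream.fs, t=stream.t.copy(),
        acc=R @ stream.acc, gyro=R @ stream.gyro, mag=R @ stream.mag,
        quat=quat)
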