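"""Gait-event detection, multi-sensor synchronization and time normalization.

Three detectors locate heel strikes, one per sensing modality:

* optical heel marker: heel strike where the anteroposterior heel velocity
  crosses zero downward immediately after a swing phase (sustained positive
  velocity);
* instrumented insole: heel strike / toe off where the vertical GRF crosses
  the 20 N threshold with positive / negative slope (crossing times are
  linearly interpolated between samples);
* shank IMU: heel strike at the first of the two deepest local minima of the
  mediolateral shank angular velocity within each stance region.

All streams are then shifted so their first heel strikes coincide with the
marker-based heel strike and cropped to the common interval, and cycles are
linearly resampled to a 101-point gait-percent vector (0-100 % inclusive,
making 0/30/60/80 % exact grid points).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .signal_io import ImuStream, InsoleStream, MarkerTrace

__all__ = [
    "GaitEvents", "CycleMatrix", "EventSequenceError", "SynchronizationError",
    "detect_hs_mocap", "detect_events_insole", "detect_hs_imu",
    "synchronize", "normalize_to_gait_percent", "ensemble_average",
    "write_events", "GRF_THRESHOLD_N",
]

logger = logging.getLogger(__name__)

GRF_THRESHOLD_N = 20.0


class EventSequenceError(ValueError):
    """Detected events do not alternate heel strike / toe off."""


class SynchronizationError(ValueError):
    """Streams do not overlap after temporal alignment."""


@dataclass
class GaitEvents:
    """Heel-strike/toe-off times and per-cycle stance fractions.

    ``hs_times`` has ``n_cycles + 1`` entries (cycle k spans
    ``hs_times[k]..hs_times[k+1]``); ``to_times[k]`` lies inside cycle k.
    """

    hs_times: np.ndarray
    to_times: np.ndarray
    stance_fraction: np.ndarray

    def __post_init__(self):
        self.hs_times = np.asarray(self.hs_times, dtype=float)
        self.to_times = np.asarray(self.to_times, dtype=float)
        self.stance_fraction = np.asarray(self.stance_fraction, dtype=float)
        if np.any(np.diff(self.hs_times) <= 0):
            raise EventSequenceError("heel strikes must be strictly increasing")
        n = self.n_cycles
        if self.to_times.size < n or self.stance_fraction.size != n:
            raise EventSequenceError("need one toe off per complete cycle")
        for k in range(n):
            if not self.hs_times[k] < self.to_times[k] < self.hs_times[k + 1]:
                raise EventSequenceError(
                    "each toe off must lie strictly between heel strikes")
        if n and not np.all((self.stance_fraction > 0) &
                            (self.stance_fraction < 1)):
            raise EventSequenceError("stance fractions must lie in (0, 1)")

    @property
    def n_cycles(self):
        return max(self.hs_times.size - 1, 0)


@dataclass
class CycleMatrix:
    """Cycles x 101 gait-percent matrix of one metric."""

    metric_name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CycleMatrix must be finite")

    @property
    def n_cycles(self):
        return self.values.shape[0]

    @property
    def gait_percent(self):
        return np.linspace(0.0, 100.0, self.values.shape[1])


def _interp_crossing(t, y, i, level=0.0):
    """Time where y crosses `level` between samples i and i+1 (linear)."""
    y0, y1 = y[i] - level, y[i + 1] - level
    if y1 == y0:
        return t[i]
    return t[i] + (t[i + 1] - t[i]) * (-y0) / (y1 - y0)


def detect_hs_mocap(heel, swing_threshold=0.2, min_swing_s=0.1):
    """Heel strikes from the anteroposterior heel-marker velocity.

    A swing phase is a contiguous interval with AP velocity above
    ``swing_threshold`` (m/s) lasting at least ``min_swing_s``; the heel strike
    is the first downward zero crossing of the AP velocity at or after the end
    of each swing phase.  The caller is expected to low-pass filter the trace
    (6 Hz) beforehand.  Returns a list of times (s); empty when no swing
    phase qualifies.
    """
    t = heel.t
    v = np.gradient(heel.pos[0], t)
    above = v > swing_threshold
    # swing intervals [i0, i1) of sustained positive AP velocity
    starts = list(np.flatnonzero(np.diff(above.astype(int)) == 1) + 1)
    if above[0]:
        starts.insert(0, 0)
    events = []
    for i0 in starts:
        i1 = i0
        while i1 < v.size and above[i1]:
            i1 += 1
        if t[min(i1, v.size - 1)] - t[i0] < min_swing_s:
            continue
        # first downward zero crossing at/after the swing end
        j = i1 - 1
        while j < v.size - 1:
            if v[j] > 0.0 >= v[j + 1]:
                events.append(_interp_crossing(t, v, j))
                break
            j += 1
    return events


def detect_events_insole(insole, threshold=GRF_THRESHOLD_N):
    """Heel strikes and toe offs from threshold crossings of the vertical GRF.

    Heel strike: upward crossing of ``threshold`` (positive slope); toe off:
    subsequent downward crossing.  Crossing times are linearly interpolated.
    Stance fraction of cycle k is ``(to_k - hs_k) / (hs_{k+1} - hs_k)``.
    """
    t, g = insole.t, insole.grf_v
    above = g > threshold
    d = np.diff(above.astype(int))
    up = np.flatnonzero(d == 1)
    down = np.flatnonzero(d == -1)
    crossings = sorted(
        [(int(i), +1) for i in up] + [(int(i), -1) for i in down])
    # drop a leading toe off (trial starting mid-stance) for pairing
    while crossings and crossings[0][1] == -1:
        crossings.pop(0)
    kinds = [k for _, k in crossings]
    if any(a == b for a, b in zip(kinds, kinds[1:])):
        raise EventSequenceError("GRF threshold crossings do not alternate")
    hs = [_interp_crossing(t, g, i, threshold) for i, k in crossings if k == +1]
    to = [_interp_crossing(t, g, i, threshold) for i, k in crossings if k == -1]
    hs = np.asarray(hs)
    to = np.asarray(to[: len(hs)])  # at most one toe off per heel strike
    n = len(hs) - 1
    stance = (to[:n] - hs[:n]) / np.diff(hs)[:n] if n > 0 else np.empty(0)
    return GaitEvents(hs_times=hs, to_times=to, stance_fraction=stance)


def detect_hs_imu(shank, stance_windows=None, pad_fraction=0.08,
                  min_prominence=0.01):
    """Heel strikes from the mediolateral shank angular velocity.

    Within each candidate stance region the detector finds the first (in time)
    of the two deepest local minima of the mediolateral gyro channel.  The
    stream is expected in the segment frame (rotated back from the as-worn
    mounting) with the gyro low-pass filtered at 2.3 Hz.

    Candidate regions come from insole stance windows ``(hs, to)`` when
    available, padded backward by ``pad_fraction`` of the cycle so the dip at
    contact is inside the region; otherwise regions span successive swing
    peaks of the gyro signal.
    """
    t = shank.t
    w = shank.gyro[2]
    from scipy.signal import find_peaks

    regions = []
    if stance_windows is not None and len(stance_windows) > 0:
        windows = list(stance_windows)
        cycle = np.median(np.diff([w0 for w0, _ in windows])) \
            if len(windows) > 1 else (windows[0][1] - windows[0][0]) / 0.67
        for w0, w1 in windows:
            regions.append((w0 - pad_fraction * cycle, w1))
    else:
        peaks, _ = find_peaks(w, prominence=max(0.2 * np.ptp(w), 1e-12))
        for a, b in zip(peaks[:-1], peaks[1:]):
            regions.append((t[a], t[b]))
    events = []
    for t0, t1 in regions:
        sel = (t >= t0) & (t <= t1)
        if sel.sum() < 5:
            logger.info("stance region %.3f-%.3f s too short; skipped", t0, t1)
            continue
        seg = w[sel]
        ts = t[sel]
        minima, _ = find_peaks(-seg, prominence=min_prominence)
        if minima.size < 2:
            logger.info("fewer than two gyro minima in region %.3f-%.3f s; "
                        "skipped", t0, t1)
            continue
        deepest = minima[np.argsort(seg[minima])[:2]]
        i = int(deepest.min())
        # sub-sample refinement: parabola through the minimum and neighbours
        if 0 < i < seg.size - 1:
            denom = seg[i - 1] - 2.0 * seg[i] + seg[i + 1]
            shift = 0.5 * (seg[i - 1] - seg[i + 1]) / denom if denom > 0 else 0.0
            events.append(ts[i] + np.clip(shift, -1.0, 1.0) / shank.fs)
        else:
            events.append(ts[i])
    return events


def _crop_to_grid(stream, t_start, t_end, fs):
    """Interpolate a (shifted) stream onto the uniform grid [t_start, t_end]."""
    n = int(np.floor((t_end - t_start) * fs)) + 1
    grid = t_start + np.arange(n) / fs
    if isinstance(stream, ImuStream):
        def interp_rows(arr):
            return np.vstack([np.interp(grid, stream.t, row) for row in arr])
        quat = interp_rows(stream.quat)
        quat /= np.linalg.norm(quat, axis=0)
        return ImuStream(segment_label=stream.segment_label, fs=fs, t=grid,
                         acc=interp_rows(stream.acc),
                         gyro=interp_rows(stream.gyro),
                         mag=interp_rows(stream.mag), quat=quat)
    if isinstance(stream, InsoleStream):
        return InsoleStream(fs=fs, t=grid,
                            grf_v=np.interp(grid, stream.t, stream.grf_v))
    return MarkerTrace(name=stream.name, fs=fs, t=grid,
                       pos=np.vstack([np.interp(grid, stream.t, row)
                                      for row in stream.pos]))


def synchronize(mocap_hs, imu_streams, insole, imu_hs, insole_hs, fs=128.0):
    """Shift IMU and insole streams so their first heel strikes align with the
    marker-based heel strike, then crop everything to the common interval.

    Parameters
    ----------
    mocap_hs, imu_hs, insole_hs : first heel-strike time (s) per modality
    imu_streams : one ImuStream or a list sharing ``imu_hs``

    Returns ``(imu_streams_like_input, insole, (t_start, t_end))`` with all
    streams on a shared uniform ``fs`` grid starting at ``t_start``.
    """
    single = isinstance(imu_streams, ImuStream)
    imus = [imu_streams] if single else list(imu_streams)
    lag_imu = mocap_hs - imu_hs
    lag_ins = mocap_hs - insole_hs
    shifted_imus = [dataclasses.replace(s.copy(), t=s.t + lag_imu)
                    for s in imus]
    shifted_ins = dataclasses.replace(insole.copy(), t=insole.t + lag_ins)
    t_start = max([s.t[0] for s in shifted_imus] + [shifted_ins.t[0]])
    t_end = min([s.t[-1] for s in shifted_imus] + [shifted_ins.t[-1]])
    if t_end - t_start <= 1.0 / fs:
        raise SynchronizationError("streams do not overlap after alignment")
    out_imus = [_crop_to_grid(s, t_start, t_end, fs) for s in shifted_imus]
    out_ins = _crop_to_grid(shifted_ins, t_start, t_end, fs)
    return (out_imus[0] if single else out_imus, out_ins, (t_start, t_end))


def normalize_to_gait_percent(series, fs, events, n_points=101, t0=0.0,
                              metric_name="metric", units=""):
    """Resample each complete heel-strike-to-heel-strike cycle to a fixed
    gait-percent vector (0-100 % inclusive).

    ``series`` is sampled uniformly at ``fs`` starting at time ``t0``.
    Incomplete leading/trailing cycles are discarded by construction of
    ``events``.
    """
    series = np.asarray(series, dtype=float)
    t = t0 + np.arange(series.size) / fs
    rows = []
    for k in range(events.n_cycles):
        a, b = events.hs_times[k], events.hs_times[k + 1]
        if a < t[0] - 0.5 / fs or b > t[-1] + 0.5 / fs:
            logger.info("cycle %d outside the sampled window; discarded", k)
            continue
        tq = np.linspace(a, b, n_points)
        rows.append(np.interp(tq, t, series))
    if not rows:
        raise ValueError("no complete gait cycle inside the sampled window")
    return CycleMatrix(metric_name=metric_name, values=np.vstack(rows),
                       units=units)


def ensemble_average(cycles):
    """Pointwise mean and sample SD across rows of a CycleMatrix (or a stacked
    array of per-subject means)."""
    values = cycles.values if isinstance(cycles, CycleMatrix) else \
        np.atleast_2d(np.asarray(cycles, dtype=float))
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else \
        np.zeros(values.shape[1])
    return mean, sd


def write_events(events, path):
    """Write events as delimited text: cycle_index, hs, to, stance_fraction."""
    import pandas as pd

    n = events.n_cycles
    pd.DataFrame({
        "cycle_index": np.arange(n),
        "hs_time_s": events.hs_times[:n],
        "to_time_s": events.to_times[:n],
        "stance_fraction": events.stance_fraction,
    }).to_csv(path, index=False, float_format="%.9g")
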