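"""Trial pre-processing pipeline: filtering, synchronization, event detection
and feature/target matrix construction for the wearable-ANN workflow.

Steps per trial (mirroring the laboratory recipe):

1. low-pass filter insole GRF and IMU vector channels at 10 Hz
   (quaternions are left unfiltered and stay unit norm),
2. resample the 100 Hz insole onto the 128 Hz IMU clock,
3. detect first heel strikes per modality — heel marker (6 Hz filtered AP
   velocity zero crossing), insole (20 N threshold), shank IMU (gyro rotated
   back from the as-worn mounting by the goniometric angle, filtered at
   2.3 Hz, dip detection) — and shift/crop all streams to the marker-based
   heel strike,
4. build the 28-column feature matrix (2 x 13 IMU channels, vertical GRF,
   activity duration) and the 4-column target matrix from the trial's
   ground-truth curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gait_events as ge
from . import signal_io as sio
from .signal_io import FilterSpec

__all__ = ["PreparedTrial", "prepare_trial", "build_features"]

IMU_FILTER = FilterSpec(cutoff_hz=10.0)
INSOLE_FILTER = FilterSpec(cutoff_hz=10.0)
MARKER_FILTER = FilterSpec(cutoff_hz=6.0)
SHANK_EVENT_FILTER = FilterSpec(cutoff_hz=2.3)
TARGET_FS = 128.0


@dataclass
class PreparedTrial:
    """Synchronized, filtered trial ready for training/evaluation."""

    X: np.ndarray          # (N, 28) features
    Y: np.ndarray          # (N, 4) targets (ground truth on the synced grid)
    fs: float
    t0: float
    events: ge.GaitEvents  # insole events on the synchronized time base
    subject_index: int
    meta: dict


def _filter_imu(stream, spec):
    out = stream.copy()
    for name in ("acc", "gyro", "mag"):
        arr = getattr(out, name)
        setattr(out, name,
                np.vstack([sio.lowpass(row, out.fs, spec) for row in arr]))
    return out


def build_features(shank, thigh, insole, duration_s):
    """Stack the 28 per-timestep ANN inputs."""
    n = shank.n_samples
    if thigh.n_samples != n or insole.n_samples != n:
        raise ValueError("streams must share the synchronized grid")
    cols = [shank.acc, shank.gyro, shank.mag, shank.quat,
            thigh.acc, thigh.gyro, thigh.mag, thigh.quat]
    X = np.vstack(cols + [insole.grf_v[None, :],
                          np.full((1, n), duration_s)]).T
    return X


def prepare_trial(trial, mount_angle_deg=None):
    """Pre-process one :class:`~stairhip.synth.TrialRecord`.

    ``mount_angle_deg`` is the goniometrically captured shank-mounting angle;
    by default the trial's recorded measurement is used.
    """
    if mount_angle_deg is None:
        mount_angle_deg = trial.meta.get("mount_angle_deg",
                                         sio.SHANK_MOUNT_ANGLE_DEG)
    duration = trial.meta.get("duration_s",
                              trial.shank_imu.t[-1] - trial.shank_imu.t[0])

    shank = _filter_imu(trial.shank_imu, IMU_FILTER)
    thigh = _filter_imu(trial.thigh_imu, IMU_FILTER)
    grf_f = sio.lowpass(trial.insole.grf_v, trial.insole.fs, INSOLE_FILTER)
    grf_128 = sio.resample_to(grf_f, trial.insole.fs, TARGET_FS)
    insole = sio.InsoleStream(
        fs=TARGET_FS,
        t=trial.insole.t[0] + np.arange(grf_128.size) / TARGET_FS,
        grf_v=grf_128)

    # per-modality first heel strikes
    heel = trial.heel.copy()
    heel.pos = np.vstack([sio.lowpass(row, heel.fs, MARKER_FILTER)
                          for row in heel.pos])
    mocap_hs = ge.detect_hs_mocap(heel)
    if not mocap_hs:
        raise ge.EventSequenceError("no marker-based heel strike found")
    insole_events = ge.detect_events_insole(insole)
    if insole_events.hs_times.size == 0:
        raise ge.EventSequenceError("no insole heel strike found")
    shank_seg = sio.rotate_shank_imu(trial.shank_imu, mount_angle_deg)
    shank_seg.gyro[2] = sio.lowpass(shank_seg.gyro[2], shank_seg.fs,
                                    SHANK_EVENT_FILTER)
    windows = list(zip(insole_events.hs_times[:-1], insole_events.to_times))
    imu_hs = ge.detect_hs_imu(shank_seg, stance_windows=windows or None)
    if not imu_hs:
        raise ge.EventSequenceError("no IMU heel strike found")

    (shank_s, thigh_s), insole_s, (t0, t1) = ge.synchronize(
        mocap_hs[0], [shank, thigh], insole,
        imu_hs=imu_hs[0], insole_hs=insole_events.hs_times[0], fs=TARGET_FS)

    events = ge.detect_events_insole(insole_s)
    if events.n_cycles < 1:
        raise ge.EventSequenceError("no complete gait cycle after sync")

    X = build_features(shank_s, thigh_s, insole_s, duration)
    grid = shank_s.t
    Y = np.column_stack([
        np.interp(grid, trial.truth["t"], trial.truth[name])
        for name in ("sagittal_angle", "sagittal_moment",
                     "frontal_angle", "frontal_moment")])
    return PreparedTrial(X=X, Y=Y, fs=TARGET_FS, t0=t0, events=events,
                         subject_index=trial.meta.get("subject_index", -1),
                         meta=dict(trial.meta))
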