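"""Synthetic stair-ascent cohort generator.

Builds fully self-consistent multi-modal trials: a sampled subject, jittered
ground-truth hip angle/moment curves, a planar pose from the kinematic
templates, virtual IMU streams (128 Hz) for shank and thigh, a 100 Hz insole
vertical-GRF stream and a 128 Hz heel-marker trace.  Ground-truth heel-strike
times sit exactly at the template cycle boundaries; the GRF template crosses
the 20 N detection threshold at those boundaries by construction, the heel
anteroposterior velocity crosses zero there (a small foot-angle correction
cancels the residual heel velocity at contact per subject), and the shank
angular-velocity template carries its characteristic double dip at the start
of stance.

Ground-truth moments are template-defined rather than re-derived from the
template GRF by inverse dynamics, so the printed calibration peaks hold
exactly; dynamic consistency of the inverse-dynamics surrogate is tested
separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dynamics, templates as tpl
from .dynamics import Subject, forward_kinematics, simulate_imu
from .signal_io import ImuStream, InsoleStream, MarkerTrace, \
    SHANK_MOUNT_ANGLE_DEG

__all__ = ["TrialRecord", "sample_subject", "generate_trial",
           "generate_cohort", "DEFAULT_NOISE_SD", "COHORT_HEIGHT_M",
           "COHORT_MASS_KG"]

COHORT_HEIGHT_M = (1.74, 0.08)   # mean, SD (m)
COHORT_MASS_KG = (81.6, 19.5)    # mean, SD (kg)
SHANK_MOUNT_SD_DEG = 6.6

IMU_FS = 128.0
INSOLE_FS = 100.0
DEFAULT_DURATION_S = 30.0
DEFAULT_LEAD_IN_S = 0.8

#: default additive noise SDs, small relative to signal ranges and consistent
#: with consumer-grade sensors
DEFAULT_NOISE_SD = {
    "gyro": 0.02,    # rad/s
    "acc": 0.2,      # m/s^2
    "mag": 0.005,    # a.u.
    "quat": 0.002,   # rad (small random rotation)
    "grf": 5.0,      # N
    "marker": 0.0005,  # m
}

TARGET_NAMES = ("sagittal_angle", "sagittal_moment",
                "frontal_angle", "frontal_moment")
TARGET_UNITS = ("deg", "Nm/kg", "deg", "Nm/kg")


@dataclass
class TrialRecord:
    """One synchronized multi-modal synthetic trial plus its ground truth."""

    subject: Subject
    shank_imu: ImuStream
    thigh_imu: ImuStream
    insole: InsoleStream
    heel: MarkerTrace
    truth: dict
    meta: dict


def sample_subject(seed):
    """Draw a subject from the cohort statistics (positive-truncated normals)."""
    rng = np.random.default_rng(seed)
    height = 0.0
    while height <= 1.0:
        height = rng.normal(*COHORT_HEIGHT_M)
    mass = 0.0
    while mass <= 20.0:
        mass = rng.normal(*COHORT_MASS_KG)
    return Subject.from_anthropometry(height, mass)


def _jittered(curve, rng, scale_sd, offset_sd, grid=tpl.GAIT_GRID):
    """Per-subject amplitude scaling about the curve mean plus a small offset."""
    mean = float(np.mean(curve(grid)))
    s = rng.normal(1.0, scale_sd)
    off = rng.normal(0.0, offset_sd)
    return curve.scaled(s).shifted(mean * (1.0 - s) + off)


def _foot_correction_gain(subject, theta_t, theta_s, theta_f, correction):
    """Gain on the foot-angle correction bump that zeroes the heel AP velocity
    at heel strike (first-order, reference contact p = 0)."""
    d2r = np.deg2rad(1.0)
    lt, ls = subject.thigh_len_m, subject.shank_len_m
    rh = dynamics.HEEL_OFFSET_FRACTION * subject.foot_len_m
    phi = np.deg2rad(dynamics.HEEL_OFFSET_ANGLE_DEG)
    base = (lt * np.cos(np.deg2rad(theta_t(0.0))) * theta_t.derivative(0.0)
            + ls * np.cos(np.deg2rad(theta_s(0.0))) * theta_s.derivative(0.0)
            + rh * np.cos(np.deg2rad(theta_f(0.0)) + phi)
            * theta_f.derivative(0.0)) * d2r
    lever = rh * np.cos(np.deg2rad(theta_f(0.0)) + phi) * d2r
    slope = correction.derivative(0.0)
    if abs(lever * slope) < 1e-12:
        return 0.0
    return -base / (lever * slope)


def generate_trial(subject, template=None, duration_s=DEFAULT_DURATION_S,
                   noise_sd=None, seed=0, lead_in_s=DEFAULT_LEAD_IN_S,
                   mount_angle_deg=None):
    """Generate one synthetic trial for ``subject``.

    ``noise_sd`` overrides entries of :data:`DEFAULT_NOISE_SD`; pass
    ``{"all": 0.0}`` (or zeros) for a noise-free trial.
    """
    if template is None:
        template = tpl.default_templates()
    noise = dict(DEFAULT_NOISE_SD)
    if noise_sd:
        if "all" in noise_sd:
            noise = {k: noise_sd["all"] for k in noise}
        else:
            noise.update(noise_sd)
    rng = np.random.default_rng(seed)

    # per-subject timing and curve jitter
    cycle_s = float(np.clip(rng.normal(template.cycle_duration_s,
                                       template.cycle_duration_sd_s),
                            1.2, 4.0))
    stance = float(np.clip(rng.normal(template.stance_fraction,
                                      template.stance_fraction_sd),
                           0.5, 0.8))
    amp, odeg, onm = (template.amplitude_jitter_sd,
                      template.offset_jitter_deg, template.offset_jitter_nmkg)
    sag_angle = _jittered(template.sagittal_angle, rng, amp, odeg)
    sag_moment = _jittered(template.sagittal_moment, rng, amp, onm)
    fro_angle = _jittered(template.frontal_angle, rng, amp, odeg)
    fro_moment = _jittered(template.frontal_moment, rng, amp, onm)
    shank_angle = _jittered(template.shank_angle, rng, 0.04, 0.5)
    foot_base = _jittered(template.foot_angle, rng, 0.04, 0.5)
    kappa = _foot_correction_gain(subject, sag_angle, shank_angle, foot_base,
                                  template.foot_correction)
    if mount_angle_deg is None:
        mount_angle_deg = rng.normal(SHANK_MOUNT_ANGLE_DEG, SHANK_MOUNT_SD_DEG)

    def foot_angle(p):
        return foot_base(p) + kappa * template.foot_correction(p)

    # ground-truth events: heel strikes at template cycle boundaries
    n_cycles = int(np.floor((duration_s - lead_in_s) / cycle_s - 1e-9))
    hs_times = lead_in_s + cycle_s * np.arange(n_cycles + 1)
    to_times = hs_times[:-1] + stance * cycle_s

    t128 = np.arange(int(round(duration_s * IMU_FS))) / IMU_FS
    p128 = (t128 - lead_in_s) / cycle_s * 100.0
    theta_t = sag_angle(p128)
    theta_s = shank_angle(p128)
    theta_f = foot_angle(p128)
    frontal = fro_angle(p128)
    pose = forward_kinematics(
        hip_deg=theta_t, knee_deg=theta_t - theta_s,
        ankle_deg=theta_f - theta_s, subject=subject, fs=IMU_FS,
        hip_frontal_deg=frontal, t0=0.0)

    child = rng.spawn(4)
    shank_imu = simulate_imu(pose, "shank", mount_fraction=0.45,
                             mount_angle_deg=mount_angle_deg,
                             noise_sd=noise, seed=child[0])
    thigh_imu = simulate_imu(pose, "thigh", mount_fraction=0.5,
                             mount_angle_deg=0.0, noise_sd=noise,
                             seed=child[1])
    heel = pose.heel_marker()
    if noise["marker"]:
        mrng = np.random.default_rng(child[2])
        heel.pos = heel.pos + mrng.normal(0.0, noise["marker"], heel.pos.shape)

    t100 = np.arange(int(round(duration_s * INSOLE_FS))) / INSOLE_FS
    p100 = (t100 - lead_in_s) / cycle_s * 100.0
    grf = tpl.grf_template(p100, subject.mass_kg, stance)
    grf[t100 < lead_in_s - 0.05 * cycle_s] = 0.0  # nothing before first contact
    if noise["grf"]:
        grng = np.random.default_rng(child[3])
        grf = grf + grng.normal(0.0, noise["grf"], grf.shape)
    insole = InsoleStream(fs=INSOLE_FS, t=t100, grf_v=np.clip(grf, 0.0, None))

    truth = {
        "t": t128,
        "sagittal_angle": theta_t,
        "sagittal_moment": sag_moment(p128),
        "frontal_angle": frontal,
        "frontal_moment": fro_moment(p128),
        "hs_times": hs_times,
        "to_times": to_times,
        "stance_fraction": np.full(n_cycles, stance),
        "cycle_duration_s": cycle_s,
    }
    meta = {
        "seed": seed,
        "duration_s": duration_s,
        "lead_in_s": lead_in_s,
        "noise_sd": noise,
        "n_cycles": n_cycles,
        "mount_angle_deg": float(mount_angle_deg),
        "stance_fraction": stance,
        "cycle_duration_s": cycle_s,
    }
    return TrialRecord(subject=subject, shank_imu=shank_imu,
                       thigh_imu=thigh_imu, insole=insole, heel=heel,
                       truth=truth, meta=meta)


def generate_cohort(n_subjects=17, template=None, duration_s=DEFAULT_DURATION_S,
                    noise_sd=None, seed=0):
    """Generate a cohort of synthetic trials (one trial per subject)."""
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    ss = np.random.SeedSequence(seed)
    trials = []
    for k, child in enumerate(ss.spawn(n_subjects)):
        subj_seed, trial_seed = child.spawn(2)
        subject = sample_subject(subj_seed)
        trial = generate_trial(subject, template=template,
                               duration_s=duration_s, noise_sd=noise_sd,
                               seed=trial_seed)
        trial.meta["subject_index"] = k
        trial.meta["master_seed"] = seed
        trials.append(trial)
    return trials


# ---------------------------------------------------------------------------
# cohort directory I/O (one directory per subject, delimited-text schemas)

def write_cohort(trials, outdir, force=False):
    """Write a cohort to disk: per-subject stream CSVs, ground-truth curves,
    subject anthropometrics and a manifest with every seed/parameter needed
    for exact reproduction."""
    import json
    from pathlib import Path

    import pandas as pd

    from . import signal_io as sio

    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"n_subjects": len(trials), "subjects": []}
    for k, tr in enumerate(trials):
        sub = out / f"subject_{k:02d}"
        sub.mkdir(exist_ok=True)
        sio.write_stream(tr.shank_imu, sub / "imu_shank.csv")
        sio.write_stream(tr.thigh_imu, sub / "imu_thigh.csv")
        sio.write_stream(tr.insole, sub / "insole.csv")
        sio.write_stream(tr.heel, sub / "heel.csv")
        truth = pd.DataFrame({"t": tr.truth["t"],
                              **{n: tr.truth[n] for n in TARGET_NAMES}})
        truth.to_csv(sub / "truth.csv", index=False, float_format="%.9g")
        events = pd.DataFrame({
            "hs_time_s": tr.truth["hs_times"],
            "to_time_s": np.append(tr.truth["to_times"], np.nan),
            "stance_fraction": np.append(tr.truth["stance_fraction"], np.nan),
        })
        events.to_csv(sub / "truth_events.csv", index=False,
                      float_format="%.9g")
        info = {
            "subject": {"height_m": tr.subject.height_m,
                        "mass_kg": tr.subject.mass_kg,
                        "thigh_len_m": tr.subject.thigh_len_m,
                        "shank_len_m": tr.subject.shank_len_m,
                        "foot_len_m": tr.subject.foot_len_m},
            "meta": {key: (val.item() if isinstance(val, np.generic) else
                           val if isinstance(val, (int, float, str, bool,
                                                   dict, list, type(None)))
                           else str(val))
                     for key, val in tr.meta.items()},
        }
        with open(sub / "subject.json", "w") as fh:
            json.dump(info, fh, indent=1)
        manifest["subjects"].append(f"subject_{k:02d}")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def load_cohort(cohort_dir):
    """Load a cohort written by :func:`write_cohort`."""
    import json
    from pathlib import Path

    import pandas as pd

    from . import signal_io as sio

    out = Path(cohort_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    trials = []
    for name in manifest["subjects"]:
        sub = out / name
        with open(sub / "subject.json") as fh:
            info = json.load(fh)
        subject = Subject(**info["subject"])
        truth_df = pd.read_csv(sub / "truth.csv")
        events_df = pd.read_csv(sub / "truth_events.csv")
        hs = events_df["hs_time_s"].to_numpy()
        truth = {"t": truth_df["t"].to_numpy(),
                 **{n: truth_df[n].to_numpy() for n in TARGET_NAMES},
                 "hs_times": hs,
                 "to_times": events_df["to_time_s"].to_numpy()[:-1],
                 "stance_fraction":
                     events_df["stance_fraction"].to_numpy()[:-1],
                 "cycle_duration_s": info["meta"].get("cycle_duration_s")}
        trials.append(TrialRecord(
            subject=subject,
            shank_imu=sio.read_stream(sub / "imu_shank.csv", "imu", "shank"),
            thigh_imu=sio.read_stream(sub / "imu_thigh.csv", "imu", "thigh"),
            insole=sio.read_stream(sub / "insole.csv", "insole"),
            heel=sio.read_stream(sub / "heel.csv", "marker"),
            truth=truth, meta=info["meta"]))
    return trials
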