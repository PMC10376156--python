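"""Planar link-segment surrogate of the laboratory gold-standard workflow.

A three-segment chain (thigh, shank, foot) hangs from a pelvis-fixed hip
joint.  Sagittal-plane segment orientations are measured from the downward
vertical, flexion positive (segment carried anteriorly); the frontal plane is
treated quasi-statically with the whole limb tilted by the hip
adduction/abduction angle (adduction positive).

The module provides

* forward kinematics (joint angles -> joint centres, talus point, heel
  marker),
* virtual IMU simulation (gyro/accelerometer/magnetometer/orientation of a
  segment-mounted sensor, including the as-worn longitudinal mounting offset
  of the shank sensor),
* bottom-up Newton-Euler inverse dynamics of the hip with the vertical GRF
  applied at the talus, mass-normalized output (Nm/kg).

Anthropometric segment parameters are classic Dempster cadaver fractions
(mass, centre-of-mass location from the proximal joint, radius of gyration
about the COM, all as fractions of body mass / segment length; segment
lengths as fractions of stature from Drillis & Contini).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .signal_io import ImuStream, InsoleStream, MarkerTrace, \
    longitudinal_rotation_matrix

__all__ = ["Subject", "PlanarPose", "forward_kinematics", "simulate_imu",
           "inverse_dynamics_hip", "GRAVITY", "LAB_MAG_FIELD"]

GRAVITY = 9.81  # m/s^2

#: lab-frame magnetic field (a.u.): horizontal north + downward dip component
LAB_MAG_FIELD = np.array([0.40, -0.55, 0.10])

# Dempster segment fractions
SEGMENT_MASS_FRACTION = {"thigh": 0.100, "shank": 0.0465, "foot": 0.0145}
SEGMENT_COM_FRACTION = {"thigh": 0.433, "shank": 0.433, "foot": 0.500}
SEGMENT_GYRATION_FRACTION = {"thigh": 0.323, "shank": 0.302, "foot": 0.475}
# Drillis & Contini segment lengths as fractions of stature
SEGMENT_LENGTH_FRACTION = {"thigh": 0.245, "shank": 0.246, "foot": 0.152}

# heel marker offset from the ankle joint centre, in the foot frame:
# distance (m scaled by foot length) and angle from the foot long axis
HEEL_OFFSET_FRACTION = 0.35
HEEL_OFFSET_ANGLE_DEG = -105.0


@dataclass(frozen=True)
class Subject:
    """Anthropometrics of one subject."""

    height_m: float
    mass_kg: float
    thigh_len_m: float
    shank_len_m: float
    foot_len_m: float
    mass_fractions: dict = field(
        default_factory=lambda: dict(SEGMENT_MASS_FRACTION))
    com_fractions: dict = field(
        default_factory=lambda: dict(SEGMENT_COM_FRACTION))
    gyration_fractions: dict = field(
        default_factory=lambda: dict(SEGMENT_GYRATION_FRACTION))

    def __post_init__(self):
        if self.height_m <= 0 or self.mass_kg <= 0:
            raise ValueError("height and mass must be positive")
        if min(self.thigh_len_m, self.shank_len_m, self.foot_len_m) <= 0:
            raise ValueError("segment lengths must be positive")
        if sum(self.mass_fractions.values()) > 1.0:
            raise ValueError("segment mass fractions must sum to <= 1")

    @classmethod
    def from_anthropometry(cls, height_m, mass_kg):
        return cls(height_m=height_m, mass_kg=mass_kg,
                   thigh_len_m=SEGMENT_LENGTH_FRACTION["thigh"] * height_m,
                   shank_len_m=SEGMENT_LENGTH_FRACTION["shank"] * height_m,
                   foot_len_m=SEGMENT_LENGTH_FRACTION["foot"] * height_m)

    def segment_length(self, segment):
        return {"thigh": self.thigh_len_m, "shank": self.shank_len_m,
                "foot": self.foot_len_m}[segment]

    def segment_mass(self, segment):
        return self.mass_fractions[segment] * self.mass_kg

    def segment_inertia(self, segment):
        r = self.gyration_fractions[segment] * self.segment_length(segment)
        return self.segment_mass(segment) * r * r


@dataclass
class PlanarPose:
    """Time series of planar segment orientations and joint centres.

    Lab frame: x anteroposterior (anterior +), y vertical (up +),
    z mediolateral (lateral +).  The hip joint centre is the origin.
    """

    fs: float
    t: np.ndarray
    subject: Subject
    theta_thigh: np.ndarray  # rad from downward vertical, flexion +
    theta_shank: np.ndarray
    theta_foot: np.ndarray
    hip_frontal: np.ndarray | None = None  # rad, adduction +

    def __post_init__(self):
        n = self.t.size
        for name in ("theta_thigh", "theta_shank", "theta_foot"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if self.hip_frontal is not None:
            self.hip_frontal = np.asarray(self.hip_frontal, dtype=float)
            if self.hip_frontal.shape != (n,):
                raise ValueError("hip_frontal must match the time base")

    @property
    def n_samples(self):
        return self.t.size

    def _segment_end(self, origin, theta, length):
        return origin + length * np.vstack([np.sin(theta), -np.cos(theta)])

    @property
    def hip(self):
        return np.zeros((2, self.n_samples))

    @property
    def knee(self):
        return self._segment_end(self.hip, self.theta_thigh,
                                 self.subject.thigh_len_m)

    @property
    def ankle(self):
        return self._segment_end(self.knee, self.theta_shank,
                                 self.subject.shank_len_m)

    #: the talus load point coincides with the ankle joint centre
    talus = ankle

    @property
    def toe(self):
        return self._segment_end(self.ankle, self.theta_foot,
                                 self.subject.foot_len_m)

    @property
    def heel(self):
        r = HEEL_OFFSET_FRACTION * self.subject.foot_len_m
        ang = self.theta_foot + np.deg2rad(HEEL_OFFSET_ANGLE_DEG)
        return self._segment_end(self.ankle, ang, r)

    def heel_marker(self, name="heel"):
        pos = np.vstack([self.heel, np.zeros(self.n_samples)])
        return MarkerTrace(name=name, fs=self.fs, t=self.t.copy(), pos=pos)

    def segment_angle(self, segment):
        return {"thigh": self.theta_thigh, "shank": self.theta_shank,
                "foot": self.theta_foot}[segment]

    def mount_point(self, segment, fraction):
        proximal = {"thigh": self.hip, "shank": self.knee,
                    "foot": self.ankle}[segment]
        return self._segment_end(proximal, self.segment_angle(segment),
                                 fraction * self.subject.segment_length(segment))


def forward_kinematics(hip_deg, knee_deg, ankle_deg, subject, fs,
                       hip_frontal_deg=None, t0=0.0):
    """Planar forward kinematics from joint angles.

    Joint conventions: hip flexion positive (thigh anterior of vertical);
    knee flexion positive (``theta_shank = theta_thigh - knee``); ankle such
    that ``theta_foot = theta_shank + ankle`` (ankle = 90 deg puts the foot
    perpendicular to the shank).
    """
    hip = np.deg2rad(np.asarray(hip_deg, dtype=float))
    knee = np.deg2rad(np.asarray(knee_deg, dtype=float))
    ankle = np.deg2rad(np.asarray(ankle_deg, dtype=float))
    if not hip.shape == knee.shape == ankle.shape:
        raise ValueError("angle series must share length")
    t = t0 + np.arange(hip.size) / fs
    frontal = None if hip_frontal_deg is None else \
        np.deg2rad(np.asarray(hip_frontal_deg, dtype=float))
    return PlanarPose(fs=fs, t=t, subject=subject, theta_thigh=hip,
                      theta_shank=hip - knee, theta_foot=hip - knee + ankle,
                      hip_frontal=frontal)


def _derivative(arr, fs, axis=-1):
    return np.gradient(arr, 1.0 / fs, axis=axis)


def simulate_imu(pose, segment, fs=None, mount_fraction=0.5,
                 mount_angle_deg=0.0, noise_sd=None, seed=0):
    """Virtual IMU stream for a sensor strapped to ``segment``.

    The sensor frame is the segment frame (x anterior, y proximal along the
    segment, z lateral) rotated about the longitudinal axis by
    ``mount_angle_deg`` (the as-worn mounting; 121.3 deg for the anteromedial
    shank sensor).  Channels:

    * gyro: segment angular velocity in the sensor frame,
    * accelerometer: specific force (mount-point acceleration minus gravity)
      in the sensor frame,
    * magnetometer: constant lab field in the sensor frame,
    * quaternion: sensor-to-lab orientation, scalar-first.

    Additive white Gaussian noise per channel group with the given SDs
    (``{"acc", "gyro", "mag", "quat"}``; quaternion noise is a small random
    rotation angle in rad).
    """
    if fs is None:
        fs = pose.fs
    if fs != pose.fs:
        raise ValueError("pose must be sampled at the requested fs")
    sd = {"acc": 0.0, "gyro": 0.0, "mag": 0.0, "quat": 0.0}
    if noise_sd:
        sd.update(noise_sd)
    rng = np.random.default_rng(seed)
    theta = pose.segment_angle(segment)
    n = pose.n_samples
    omega = _derivative(theta, fs)
    pos = pose.mount_point(segment, mount_fraction)
    acc_lab2d = _derivative(_derivative(pos, fs), fs)
    acc_lab = np.vstack([acc_lab2d, np.zeros(n)])
    g = np.array([0.0, -GRAVITY, 0.0])
    omega_lab = np.vstack([np.zeros((2, n)), omega])

    # lab <- sensor = Rz(theta) o Ry(mount)
    c, s = np.cos(theta), np.sin(theta)
    Rz = np.zeros((n, 3, 3))
    Rz[:, 0, 0] = c
    Rz[:, 0, 1] = -s
    Rz[:, 1, 0] = s
    Rz[:, 1, 1] = c
    Rz[:, 2, 2] = 1.0
    Rm = longitudinal_rotation_matrix(mount_angle_deg)
    R = Rz @ Rm  # (n, 3, 3), lab <- sensor

    def to_sensor(v_lab):
        # v_sensor = R^T v_lab (v_lab is (3, n) or (3,))
        if v_lab.ndim == 1:
            return np.einsum("nij,i->jn", R, v_lab)
        return np.einsum("nij,in->jn", R, v_lab)

    gyro = to_sensor(omega_lab) + rng.normal(0.0, sd["gyro"], (3, n)) \
        if sd["gyro"] else to_sensor(omega_lab)
    acc = to_sensor(acc_lab - g[:, None])
    if sd["acc"]:
        acc = acc + rng.normal(0.0, sd["acc"], (3, n))
    mag = to_sensor(LAB_MAG_FIELD)
    if sd["mag"]:
        mag = mag + rng.normal(0.0, sd["mag"], (3, n))
    rot = Rotation.from_matrix(R)
    if sd["quat"]:
        axes = rng.normal(size=(n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = rng.normal(0.0, sd["quat"], n)
        rot = rot * Rotation.from_rotvec(axes * angles[:, None])
    quat = rot.as_quat()[:, [3, 0, 1, 2]].T
    quat *= np.where(quat[0] < 0, -1.0, 1.0)
    quat /= np.linalg.norm(quat, axis=0)
    return ImuStream(segment_label=segment, fs=fs, t=pose.t.copy(), acc=acc,
                     gyro=gyro, mag=mag, quat=quat)


def _cross2(r, f):
    """z-component of the planar cross product r x f."""
    return r[0] * f[1] - r[1] * f[0]


def inverse_dynamics_hip(pose, grf, subject=None, talus_shift_m=0.0):
    """Net hip moments (sagittal, frontal) in Nm/kg from bottom-up
    Newton-Euler inverse dynamics with only the vertical GRF as external load,
    applied at the talus (optionally shifted anteriorly by ``talus_shift_m``).

    Sign conventions: sagittal moment flexion-positive (stance-phase extension
    support appears negative); frontal moment adduction-positive (single-leg
    stance abduction support appears negative).  The frontal plane is
    quasi-static: inertial terms about the anteroposterior axis are neglected.
    """
    if subject is None:
        subject = pose.subject
    if subject.mass_kg <= 0:
        raise ValueError("subject mass must be positive")
    if grf.n_samples != pose.n_samples:
        raise ValueError("pose and GRF must be synchronized at the same fs")
    fs = pose.fs
    n = pose.n_samples
    fv = np.clip(grf.grf_v, 0.0, None)
    g_vec = np.array([0.0, -GRAVITY])

    joints = {"thigh": (pose.hip, pose.knee), "shank": (pose.knee, pose.ankle),
              "foot": (pose.ankle, pose.toe)}
    talus = pose.talus + np.array([[talus_shift_m], [0.0]])
    f_ext = np.vstack([np.zeros(n), fv])  # vertical GRF only

    # bottom-up: foot -> shank -> thigh
    f_distal = np.zeros((2, n))
    m_distal = np.zeros(n)
    r_distal = None
    for segment in ("foot", "shank", "thigh"):
        prox, dist = joints[segment]
        m_seg = subject.segment_mass(segment)
        i_seg = subject.segment_inertia(segment)
        theta = pose.segment_angle(segment)
        com = prox + subject.com_fractions[segment] * (dist - prox)
        a_com = _derivative(_derivative(com, fs), fs)
        alpha = _derivative(_derivative(theta, fs), fs)
        f_ext_seg = f_ext if segment == "foot" else np.zeros((2, n))
        r_ext = talus if segment == "foot" else com
        # proximal joint force: m a = F_prox + F_distal_reaction + F_ext + m g
        f_prox = m_seg * a_com - f_distal - f_ext_seg - m_seg * g_vec[:, None]
        # proximal joint moment about the segment COM
        m_prox = (i_seg * alpha
                  - m_distal
                  - _cross2(prox - com, f_prox)
                  - _cross2(dist - com, f_distal)
                  - _cross2(r_ext - com, f_ext_seg))
        # reaction passed up to the next segment's distal end
        f_distal = -f_prox
        m_distal = -m_prox
    sagittal = m_prox / subject.mass_kg

    # frontal plane, quasi-static: limb tilted by the hip adduction angle in
    # the y-z plane; moment about the anteroposterior axis at the hip
    phi = pose.hip_frontal if pose.hip_frontal is not None else np.zeros(n)
    m_ext = np.zeros(n)
    # z (lateral +) coordinates of segment COMs and talus; adduction tilts the
    # limb toward the midline (negative z)
    dist_from_hip = {"thigh": 0.0}
    l_thigh, l_shank = subject.thigh_len_m, subject.shank_len_m
    com_dist = {
        "thigh": subject.com_fractions["thigh"] * l_thigh,
        "shank": l_thigh + subject.com_fractions["shank"] * l_shank,
        "foot": l_thigh + l_shank,
    }
    talus_dist = l_thigh + l_shank
    sin_phi = np.sin(phi)
    # external moment about the hip AP axis: Mx = sum(y F_z - z F_y)
    for segment in ("thigh", "shank", "foot"):
        z = -com_dist[segment] * sin_phi
        m_ext += -z * (-GRAVITY * subject.segment_mass(segment))
    z_talus = -talus_dist * sin_phi
    m_ext += -z_talus * fv
    frontal = -m_ext / subject.mass_kg  # net (reaction) moment, adduction +
    return sagittal, frontal
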