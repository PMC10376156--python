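"""Forward kinematics, virtual IMU simulation and hip inverse dynamics."""

import numpy as np
import pytest

import stairhip as sh
from stairhip.dynamics import GRAVITY

FS = 128.0
N = 256


def _pose(subject, hip=0.0, knee=0.0, ankle=90.0, frontal=None):
    const = lambda v: np.full(N, float(v))
    return sh.forward_kinematics(
        const(hip), const(knee), const(ankle), subject, FS,
        hip_frontal_deg=None if frontal is None else const(frontal))


def static_hip_moment_oracle(pose, subject, grf_n, talus_shift_m=0.0):
    """Independent static free-body computation of the sagittal hip moment.

    Sums moments of segment weights and the vertical GRF about the hip joint
    centre (z component of r x F), then returns the internal reaction
    normalized by body mass (flexion positive).
    """
    i = pose.n_samples // 2
    chain = {"thigh": (pose.hip, pose.knee), "shank": (pose.knee, pose.ankle),
             "foot": (pose.ankle, pose.toe)}
    m_ext = 0.0
    for seg, (prox, dist) in chain.items():
        com = prox[:, i] + subject.com_fractions[seg] * (dist[:, i] - prox[:, i])
        m_ext += com[0] * (-subject.segment_mass(seg) * GRAVITY)
    m_ext += (pose.talus[0, i] + talus_shift_m) * grf_n
    return -m_ext / subject.mass_kg


def static_frontal_moment_oracle(pose, subject, grf_n):
    """Independent static free-body frontal moment (adduction positive)."""
    i = pose.n_samples // 2
    phi = pose.hip_frontal[i]
    lt, ls = subject.thigh_len_m, subject.shank_len_m
    com_d = {"thigh": subject.com_fractions["thigh"] * lt,
             "shank": lt + subject.com_fractions["shank"] * ls,
             "foot": lt + ls}
    m_ext = 0.0
    for seg, d in com_d.items():
        z = -d * np.sin(phi)
        m_ext += -z * (-subject.segment_mass(seg) * GRAVITY)
    m_ext += (lt + ls) * np.sin(phi) * grf_n
    return -m_ext / subject.mass_kg


class TestForwardKinematics:
    def test_reference_posture_stacks_vertically(self, subject):
        pose = _pose(subject, ankle=0.0)
        np.testing.assert_allclose(pose.talus[:, 0],
                                   [0.0, -(subject.thigh_len_m
                                           + subject.shank_len_m)],
                                   atol=1e-12)

    def test_hip_flexion_90_puts_knee_anterior(self, subject):
        pose = _pose(subject, hip=90.0)
        np.testing.assert_allclose(pose.knee[:, 0],
                                   [subject.thigh_len_m, 0.0], atol=1e-12)

    def test_segment_lengths_invariant_under_random_angles(self, subject):
        rng = np.random.default_rng(0)
        pose = sh.forward_kinematics(rng.uniform(-60, 90, N),
                                     rng.uniform(0, 120, N),
                                     rng.uniform(40, 130, N), subject, FS)
        for prox, dist, L in [(pose.hip, pose.knee, subject.thigh_len_m),
                              (pose.knee, pose.ankle, subject.shank_len_m),
                              (pose.ankle, pose.toe, subject.foot_len_m)]:
            np.testing.assert_allclose(
                np.linalg.norm(dist - prox, axis=0), L, atol=1e-9)

    def test_mismatched_angle_lengths_rejected(self, subject):
        with pytest.raises(ValueError, match="share length"):
            sh.forward_kinematics(np.zeros(4), np.zeros(5), np.zeros(4),
                                  subject, FS)


class TestSimulateImu:
    def test_static_pose_measures_gravity_only(self, subject):
        pose = _pose(subject, hip=20.0, knee=10.0)
        imu = sh.simulate_imu(pose, "shank", mount_angle_deg=121.3, seed=0)
        assert np.abs(imu.gyro).max() < 1e-9
        np.testing.assert_allclose(np.linalg.norm(imu.acc, axis=0), GRAVITY,
                                   atol=1e-6)

    def test_constant_angular_velocity_on_ml_channel(self, subject):
        omega = 0.8  # rad/s about the mediolateral axis
        t = np.arange(N) / FS
        hip = np.rad2deg(omega * t)
        pose = sh.forward_kinematics(hip, np.zeros(N), np.full(N, 90.0),
                                     subject, FS)
        imu = sh.simulate_imu(pose, "thigh", seed=0)
        mid = slice(4, N - 4)
        np.testing.assert_allclose(imu.gyro[2, mid], omega, atol=1e-6)
        assert np.abs(imu.gyro[:2, mid]).max() < 1e-9

    def test_seed_reproducibility(self, subject):
        pose = _pose(subject, hip=15.0)
        kw = dict(mount_angle_deg=121.3, noise_sd={"acc": 0.2, "gyro": 0.02})
        a = sh.simulate_imu(pose, "shank", seed=5, **kw)
        b = sh.simulate_imu(pose, "shank", seed=5, **kw)
        c = sh.simulate_imu(pose, "shank", seed=6, **kw)
        np.testing.assert_array_equal(a.acc, b.acc)
        np.testing.assert_array_equal(a.gyro, b.gyro)
        assert np.abs(a.acc - c.acc).max() > 0

    def test_mount_rotation_recoverable(self, subject):
        # rotating the stream back by the mounting angle recovers the
        # mediolateral gyro of the segment
        t = np.arange(N) / FS
        hip = 20.0 * np.sin(2 * np.pi * 0.5 * t)
        pose = sh.forward_kinematics(hip, np.zeros(N), np.full(N, 90.0),
                                     subject, FS)
        raw = sh.simulate_imu(pose, "shank", mount_angle_deg=121.3, seed=0)
        seg = sh.rotate_shank_imu(raw, 121.3)
        expected = np.gradient(np.deg2rad(hip), 1.0 / FS)
        np.testing.assert_allclose(seg.gyro[2], expected, atol=1e-9)
        assert np.abs(seg.gyro[:2]).max() < 1e-9


class TestInverseDynamics:
    def test_matches_static_oracle(self, subject):
        for hip, knee, frontal, bw in [(0.0, 0.0, 0.0, 1.0),
                                       (20.0, 5.0, 6.0, 1.0),
                                       (45.0, 30.0, -4.0, 0.5),
                                       (90.0, 0.0, 10.0, 0.0)]:
            pose = _pose(subject, hip=hip, knee=knee, frontal=frontal)
            grf_n = bw * subject.mass_kg * GRAVITY
            grf = sh.InsoleStream(fs=FS, t=pose.t, grf_v=np.full(N, grf_n))
            sag, fro = sh.inverse_dynamics_hip(pose, grf, subject)
            i = N // 2
            assert sag[i] == pytest.approx(
                static_hip_moment_oracle(pose, subject, grf_n), abs=1e-6)
            assert fro[i] == pytest.approx(
                static_frontal_moment_oracle(pose, subject, grf_n), abs=1e-6)

    def test_zero_grf_static_is_pure_gravity(self, subject):
        pose = _pose(subject, hip=90.0)
        grf = sh.InsoleStream(fs=FS, t=pose.t, grf_v=np.zeros(N))
        sag, _ = sh.inverse_dynamics_hip(pose, grf, subject)
        # holding the straight leg horizontal needs a flexor (positive) moment
        expected = static_hip_moment_oracle(pose, subject, 0.0)
        assert expected > 0
        assert sag[N // 2] == pytest.approx(expected, abs=1e-6)

    def test_mass_normalization_invariance(self):
        light = sh.Subject.from_anthropometry(1.74, 60.0)
        heavy = sh.Subject.from_anthropometry(1.74, 120.0)
        for subj_a, subj_b in [(light, heavy)]:
            out = []
            for subj in (subj_a, subj_b):
                pose = _pose(subj, hip=25.0, knee=10.0, frontal=5.0)
                grf = sh.InsoleStream(
                    fs=FS, t=pose.t,
                    grf_v=np.full(N, 1.1 * subj.mass_kg * GRAVITY))
                out.append(sh.inverse_dynamics_hip(pose, grf, subj))
            np.testing.assert_allclose(out[0][0], out[1][0], atol=1e-9)
            np.testing.assert_allclose(out[0][1], out[1][1], atol=1e-9)

    def test_anterior_talus_shift_increases_extension_moment(self, subject):
        pose = _pose(subject, hip=20.0, knee=5.0)
        grf = sh.InsoleStream(fs=FS, t=pose.t,
                              grf_v=np.full(N, subject.mass_kg * GRAVITY))
        base, _ = sh.inverse_dynamics_hip(pose, grf, subject)
        shifted, _ = sh.inverse_dynamics_hip(pose, grf, subject,
                                             talus_shift_m=0.01)
        i = N // 2
        assert base[i] < 0  # extension-phase support moment is negative
        assert abs(shifted[i]) > abs(base[i])

    def test_dynamic_trial_swing_phase_is_inertial_only(self, clean_trial):
        # during swing (GRF = 0) the moment must be independent of the GRF
        trial = clean_trial
        p = sh.prepare_trial(trial)
        assert p.X.shape[1] == 28  # smoke: pipeline ran

    def test_nonpositive_mass_rejected(self, subject):
        with pytest.raises(ValueError):
            sh.Subject.from_anthropometry(1.74, -5.0)


class TestSubjectSampling:
    def test_fixed_seed_reproducible(self):
        a = sh.sample_subject(42)
        b = sh.sample_subject(42)
        assert a == b

    def test_population_statistics(self):
        heights = np.array([sh.sample_subject(k).height_m
                            for k in range(10_000)])
        masses = np.array([sh.sample_subject(k).mass_kg
                           for k in range(10_000)])
        assert heights.mean() == pytest.approx(1.74, abs=0.01)
        assert masses.mean() == pytest.approx(81.6, abs=1.0)
        assert np.all(masses > 0)
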