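"""Event detection, synchronization and gait-percent normalization."""

import numpy as np
import pytest

import stairhip as sh
import stairhip.gait_events as ge
import stairhip.signal_io as sio
from conftest import match_events

FS = 128.0


def _insole(grf, fs=FS):
    return sh.InsoleStream(fs=fs, t=np.arange(len(grf)) / fs, grf_v=grf)


def _marker(x, fs=FS):
    pos = np.vstack([x, np.zeros_like(x), np.zeros_like(x)])
    return sh.MarkerTrace(name="heel", fs=fs, t=np.arange(len(x)) / fs,
                          pos=pos)


class TestInsoleDetector:
    def test_square_pulse_single_cycle(self):
        grf = np.zeros(256)
        grf[64:160] = 600.0
        ev = ge.detect_events_insole(_insole(grf))
        assert ev.hs_times.size == 1 and ev.to_times.size == 1
        assert 63 / FS < ev.hs_times[0] < 65 / FS
        assert 159 / FS < ev.to_times[0] < 161 / FS

    def test_all_zero_grf_no_events(self):
        ev = ge.detect_events_insole(_insole(np.zeros(256)))
        assert ev.n_cycles == 0 and ev.hs_times.size == 0

    def test_alternation_enforced_by_construction(self):
        # two full pulses -> one complete cycle with hs < to < next hs
        grf = np.zeros(512)
        grf[50:150] = 500.0
        grf[250:350] = 500.0
        ev = ge.detect_events_insole(_insole(grf))
        assert ev.n_cycles == 1
        assert ev.hs_times[0] < ev.to_times[0] < ev.hs_times[1]

    def test_leading_midstance_ignored(self):
        grf = np.zeros(512)
        grf[:80] = 400.0  # trial starts mid-stance
        grf[200:320] = 400.0
        ev = ge.detect_events_insole(_insole(grf))
        assert ev.hs_times.size == 1

    def test_stance_fraction_on_synthetic_train(self, noisy_trial):
        grf = sio.lowpass(noisy_trial.insole.grf_v, 100.0,
                          sh.FilterSpec(10.0))
        g128 = sio.resample_to(grf, 100.0, 128.0)
        ev = ge.detect_events_insole(_insole(g128))
        truth = noisy_trial.truth["stance_fraction"].mean()
        assert ev.stance_fraction.mean() == pytest.approx(truth, abs=0.01)


class TestMocapDetector:
    def test_stationary_marker_no_events(self):
        assert ge.detect_hs_mocap(_marker(np.full(512, 0.3))) == []

    def test_single_synthetic_stride(self):
        # one positive velocity hump (swing) ending at a known zero crossing
        t = np.arange(512) / FS
        v = np.where((t > 1.0) & (t < 2.0), np.sin(np.pi * (t - 1.0)), 0.0)
        x = np.cumsum(v) / FS
        events = ge.detect_hs_mocap(_marker(x))
        assert len(events) == 1
        assert events[0] == pytest.approx(2.0, abs=2 / FS)

    def test_recovers_generator_contact_times(self, small_cohort):
        for trial in small_cohort:
            heel = trial.heel.copy()
            heel.pos = np.vstack([sio.lowpass(r, heel.fs, sh.FilterSpec(6.0))
                                  for r in heel.pos])
            det = ge.detect_hs_mocap(heel)
            truth = trial.truth["hs_times"][:-1]
            err = match_events(det, truth, 0.5)
            assert np.all(np.isfinite(err))
            assert np.nanmax(np.abs(err)) < 2.0 / FS


class TestImuDetector:
    def test_constant_signal_no_events(self, subject):
        n = 512
        q = np.zeros((4, n))
        q[0] = 1.0
        stream = sh.ImuStream(segment_label="shank", fs=FS,
                              t=np.arange(n) / FS, acc=np.zeros((3, n)),
                              gyro=np.zeros((3, n)), mag=np.zeros((3, n)),
                              quat=q)
        assert ge.detect_hs_imu(stream) == []

    def test_pure_sine_minima_at_analytic_positions(self):
        # omega = sin(2 pi t): minima at t = 0.75 + k; regions span the
        # swing peaks at t = 0.25 + k, each containing exactly one minimum,
        # which is skipped (fewer than two minima per region)
        n = int(6 * FS)
        t = np.arange(n) / FS
        w = np.sin(2 * np.pi * t)
        q = np.zeros((4, n))
        q[0] = 1.0
        stream = sh.ImuStream(segment_label="shank", fs=FS, t=t,
                              acc=np.zeros((3, n)), gyro=np.vstack(
                                  [np.zeros((2, n)), w[None, :]]), mag=np.zeros((3, n)),
                              quat=q)
        # with two-minima windows provided, the detector picks the sine minima
        windows = [(0.3, 2.3), (2.3, 4.3)]
        det = ge.detect_hs_imu(stream, stance_windows=windows, pad_fraction=0.0)
        assert len(det) == 2
        assert det[0] == pytest.approx(0.75, abs=2 / FS)
        assert det[1] == pytest.approx(2.75, abs=2 / FS)

    def test_recovers_generator_contact_times(self, small_cohort):
        for trial in small_cohort:
            shank = sio.rotate_shank_imu(trial.shank_imu,
                                         trial.meta["mount_angle_deg"])
            shank.gyro[2] = sio.lowpass(shank.gyro[2], FS, sh.FilterSpec(2.3))
            hs, to = trial.truth["hs_times"], trial.truth["to_times"]
            windows = list(zip(hs[:-1], to))
            det = ge.detect_hs_imu(shank, stance_windows=windows)
            err = match_events(det, hs[:-1], 0.5)
            assert np.all(np.isfinite(err))
            assert np.nanmax(np.abs(err)) < 2.0 / FS


class TestSynchronize:
    def _streams(self, trial, lag_imu, lag_ins):
        import dataclasses

        imu = trial.shank_imu.copy()
        imu = dataclasses.replace(imu, t=imu.t + lag_imu)
        grf = sio.resample_to(trial.insole.grf_v, 100.0, 128.0)
        ins = sh.InsoleStream(fs=FS, t=np.arange(grf.size) / FS + lag_ins,
                              grf_v=grf)
        return imu, ins

    def test_known_lags_are_removed(self, clean_trial):
        hs0 = clean_trial.truth["hs_times"][0]
        imu, ins = self._streams(clean_trial, +0.35, -0.20)
        imu_s, ins_s, (t0, t1) = ge.synchronize(
            hs0, imu, ins, imu_hs=hs0 + 0.35, insole_hs=hs0 - 0.20)
        ev = ge.detect_events_insole(ins_s)
        assert abs(ev.hs_times[0] - hs0) <= 0.5 / FS + 1e-9
        np.testing.assert_allclose(imu_s.t[0], ins_s.t[0])
        assert t1 > t0

    def test_zero_lags_identity(self, clean_trial):
        hs0 = clean_trial.truth["hs_times"][0]
        imu, ins = self._streams(clean_trial, 0.0, 0.0)
        imu_s, ins_s, _ = ge.synchronize(hs0, imu, ins, imu_hs=hs0,
                                         insole_hs=hs0)
        np.testing.assert_allclose(
            imu_s.gyro[:, :imu.n_samples - 2],
            imu.gyro[:, :imu.n_samples - 2], atol=1e-9)

    def test_excessive_lag_raises(self, clean_trial):
        hs0 = clean_trial.truth["hs_times"][0]
        imu, ins = self._streams(clean_trial, 0.0, 0.0)
        with pytest.raises(ge.SynchronizationError):
            ge.synchronize(hs0, imu, ins, imu_hs=hs0 + 100.0, insole_hs=hs0)


class TestNormalization:
    def _events(self):
        hs = np.array([0.0, 1.0, 2.0, 3.0])
        to = hs[:-1] + 0.67
        return ge.GaitEvents(hs_times=hs, to_times=to,
                             stance_fraction=np.full(3, 0.67))

    def test_constant_signal_constant_rows(self):
        ev = self._events()
        cm = ge.normalize_to_gait_percent(np.full(512, 2.5), FS, ev)
        assert cm.values.shape == (3, 101)
        np.testing.assert_allclose(cm.values, 2.5)

    def test_elapsed_time_gives_ramps(self):
        ev = self._events()
        t = np.arange(512) / FS
        series = np.mod(t, 1.0)  # elapsed time within each 1 s cycle
        cm = ge.normalize_to_gait_percent(series, FS, ev)
        for row in cm.values:
            np.testing.assert_allclose(row[1:-1],
                                       np.linspace(0, 1.0, 101)[1:-1],
                                       atol=0.02)

    def test_three_cycles_shape(self):
        cm = ge.normalize_to_gait_percent(np.sin(np.arange(512)), FS,
                                          self._events())
        assert cm.values.shape == (3, 101)

    def test_min_max_preserved_within_interpolation_tolerance(self):
        t = np.arange(512) / FS
        series = np.sin(2 * np.pi * t)
        cm = ge.normalize_to_gait_percent(series, FS, self._events())
        rng = series.max() - series.min()
        assert cm.values.max() == pytest.approx(series.max(), abs=0.01 * rng)

    def test_no_complete_cycle_raises(self):
        ev = ge.GaitEvents(hs_times=np.array([10.0, 11.0]),
                           to_times=np.array([10.67]),
                           stance_fraction=np.array([0.67]))
        with pytest.raises(ValueError, match="cycle"):
            ge.normalize_to_gait_percent(np.ones(64), FS, ev)


class TestEnsembleAverage:
    def test_identical_rows_zero_sd(self):
        cm = ge.CycleMatrix("m", np.tile(np.arange(101.0), (4, 1)))
        mean, sd = ge.ensemble_average(cm)
        np.testing.assert_allclose(sd, 0.0)
        np.testing.assert_allclose(mean, np.arange(101.0))

    def test_two_rows_hand_computed(self):
        cm = ge.CycleMatrix("m", np.vstack([np.zeros(101), np.full(101, 2.0)]))
        mean, sd = ge.ensemble_average(cm)
        np.testing.assert_allclose(mean, 1.0)
        np.testing.assert_allclose(sd, np.sqrt(2.0))

    def test_balanced_grand_mean_equals_mean_of_subject_means(self):
        rng = np.random.default_rng(0)
        subjects = [rng.normal(size=(5, 101)) for _ in range(3)]
        grand, _ = ge.ensemble_average(np.vstack(subjects))
        subj_means = np.vstack([s.mean(axis=0) for s in subjects])
        np.testing.assert_allclose(grand, subj_means.mean(axis=0), atol=1e-12)
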