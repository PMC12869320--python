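"""Cleaning chain: re-referencing, filtering, resampling, Tukey screen,
neighbor interpolation and edge-truncated moving-average smoothing."""

import numpy as np
import pytest

from tmrdecode import ContinuousRecording, EpochSet
from tmrdecode.epochs import DEFAULT_CHANNELS, MASTOIDS
from tmrdecode.preprocessing import (
    bandpass_center,
    interpolate_bad_channels,
    moving_average_smooth,
    rereference_mastoids,
    resample_to,
    tukey_outlier_screen,
)

ALL_CHANNELS = list(DEFAULT_CHANNELS) + list(MASTOIDS)


def make_recording(data, rate=200.0, names=None):
    names = names or [f"CH{i:02d}" for i in range(data.shape[0])]
    return ContinuousRecording(np.asarray(data, float), rate, names)


def make_epochs(trials, labels=None, names=None, rate=200.0, state="sleep"):
    trials = [np.asarray(t, float) for t in trials]
    n = len(trials)
    labels = labels if labels is not None else (np.arange(n) % 4) + 1
    names = names or list(DEFAULT_CHANNELS)[: trials[0].shape[0]]
    return EpochSet(trials=trials, labels=labels, state=state, rate=rate,
                    channel_names=names)


class TestRereference:
    def test_constant_example(self):
        data = np.zeros((60, 100))
        names = ALL_CHANNELS[:58] + list(MASTOIDS)
        data[names.index("TP9")] = 2.0
        data[names.index("TP10")] = 4.0
        data[0] = 10.0
        rec = make_recording(data, names=names)
        out = rereference_mastoids(rec)
        assert np.allclose(out.data[0], 7.0)  # 10 - (2+4)/2
        assert out.reference == "mastoids"
        assert set(MASTOIDS).isdisjoint(out.channel_names)

    def test_zero_mastoids_identity(self):
        data = np.random.default_rng(0).normal(size=(60, 50))
        names = ALL_CHANNELS[:58] + list(MASTOIDS)
        data[-2:] = 0.0
        rec = make_recording(data, names=names)
        out = rereference_mastoids(rec, drop=False)
        assert np.allclose(out.data, rec.data)
        # with mastoids zeroed the operation is idempotent
        out2 = rereference_mastoids(out, drop=False)
        assert np.allclose(out2.data, out.data)

    def test_missing_mastoid_named_in_error(self):
        rec = make_recording(np.zeros((3, 10)), names=["TP9", "Cz", "Fz"])
        with pytest.raises(ValueError, match="TP10"):
            rereference_mastoids(rec)


class TestBandpass:
    def test_stopband_and_passband(self):
        # long recording, measured away from the edges: the 0.1 Hz edge has
        # a seconds-long impulse response, so boundaries are excluded
        t = np.arange(0, 60, 1 / 200)
        sl = slice(1000, -1000)
        rec50 = make_recording(np.sin(2 * np.pi * 50 * t)[None, :])
        rec10 = make_recording(np.sin(2 * np.pi * 10 * t)[None, :])
        out50 = bandpass_center(rec50, 0.1, 30.0)
        out10 = bandpass_center(rec10, 0.1, 30.0)
        rms = lambda x: np.sqrt(np.mean(x[:, sl] ** 2))
        assert rms(out50.data) < 0.05 * rms(rec50.data)
        assert rms(out10.data) == pytest.approx(rms(rec10.data), rel=0.10)

    def test_constant_goes_to_zero(self):
        rec = make_recording(np.full((2, 1000), 7.3))
        out = bandpass_center(rec)
        assert np.allclose(out.data, 0.0, atol=1e-6)

    def test_linearity(self, rng):
        x = rng.normal(size=(1, 800))
        y = rng.normal(size=(1, 800))
        f = lambda d: bandpass_center(make_recording(d)).data
        assert np.allclose(f(2 * x + 3 * y), 2 * f(x) + 3 * f(y), atol=1e-6)

    def test_invalid_band(self):
        rec = make_recording(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            bandpass_center(rec, 10.0, 150.0)


class TestResample:
    def test_sample_count(self):
        rec = make_recording(np.zeros((2, 5000)), rate=500.0)
        out = resample_to(rec, 200.0)
        assert out.data.shape[1] == 2000
        assert out.rate == 200.0

    def test_sinusoid_preserved(self):
        t250 = np.arange(0, 4, 1 / 250)
        rec = make_recording(np.sin(2 * np.pi * 5 * t250)[None, :], rate=250.0)
        out = resample_to(rec, 200.0)
        ideal = np.sin(2 * np.pi * 5 * np.arange(out.data.shape[1]) / 200)
        r = np.corrcoef(out.data[0], ideal)[0, 1]
        assert r > 0.999

    def test_identity_and_upsampling_error(self):
        rec = make_recording(np.random.default_rng(0).normal(size=(1, 400)))
        assert np.array_equal(resample_to(rec, 200.0).data, rec.data)
        with pytest.raises(ValueError):
            resample_to(rec, 500.0)


class TestTukeyScreen:
    def _clean_epochs(self, rng, n_trials=20):
        """Identical trials: zero IQR everywhere, so only planted anomalies
        are flagged (keeps the decision tests deterministic)."""
        base = rng.normal(size=(58, 100))
        return make_epochs([base.copy() for _ in range(n_trials)],
                           names=list(DEFAULT_CHANNELS))

    def _noisy_epochs(self, rng, n_trials=20):
        return make_epochs([rng.normal(size=(58, 100)) for _ in range(n_trials)],
                           names=list(DEFAULT_CHANNELS))

    def test_identical_trials_all_keep(self):
        trial = np.random.default_rng(0).normal(size=(58, 80))
        epochs = make_epochs([trial.copy() for _ in range(10)],
                             names=list(DEFAULT_CHANNELS))
        rep = tukey_outlier_screen(epochs)
        assert not rep.bad.any()
        assert rep.decisions == ["keep"] * 10

    def test_gross_outlier_rejected(self, rng):
        epochs = self._clean_epochs(rng)
        epochs.trials[5][:30] *= 10.0  # variance x100 on 30/58 channels
        rep = tukey_outlier_screen(epochs)
        assert rep.decisions[5] == "reject"

    def test_few_bad_non_motor_channels_interpolated(self, rng):
        epochs = self._clean_epochs(rng)
        for ch in ("Fp1", "Fp2", "O1", "O2"):  # 4/58, none motor
            epochs.trials[3][epochs.channel_names.index(ch)] *= 10.0
        rep = tukey_outlier_screen(epochs)
        assert rep.decisions[3] == "interpolate"
        assert rep.frac_bad_motor[3] == 0.0
        assert rep.frac_bad[3] == pytest.approx(4 / 58)

    def test_motor_rule_overrides(self, rng):
        epochs = self._clean_epochs(rng)
        # 4/12 motor channels bad -> >25% of the motor subset
        for ch in ("C1", "C3", "CP1", "CP3"):
            epochs.trials[2][epochs.channel_names.index(ch)] *= 10.0
        rep = tukey_outlier_screen(epochs)
        assert rep.decisions[2] == "reject"

    def test_stable_under_duplicated_clean_trial(self, rng):
        epochs = self._clean_epochs(rng)
        epochs.trials[4][:20] *= 10.0
        before = tukey_outlier_screen(epochs).decisions
        dup = make_epochs(epochs.trials + [epochs.trials[0].copy()],
                          names=list(DEFAULT_CHANNELS))
        after = tukey_outlier_screen(dup).decisions
        assert after[: len(before)] == before

    def test_channel_order_invariance(self, rng):
        epochs = self._noisy_epochs(rng, 12)
        epochs.trials[1][10] *= 8.0
        rep = tukey_outlier_screen(epochs)
        perm = rng.permutation(58)
        permuted = make_epochs([t[perm] for t in epochs.trials],
                               names=[epochs.channel_names[i] for i in perm])
        rep_p = tukey_outlier_screen(permuted)
        assert rep.decisions == rep_p.decisions

    def test_too_few_trials(self, rng):
        with pytest.raises(ValueError):
            tukey_outlier_screen(self._noisy_epochs(rng, 5))


class TestInterpolation:
    def _square_setup(self):
        """Five channels: a centre with four equidistant neighbors."""
        names = ["C", "N1", "N2", "N3", "N4"]
        positions = {
            "C": np.zeros(2),
            "N1": np.array([1.0, 0.0]),
            "N2": np.array([-1.0, 0.0]),
            "N3": np.array([0.0, 1.0]),
            "N4": np.array([0.0, -1.0]),
        }
        neighbors = {"C": {"N1", "N2", "N3", "N4"},
                     **{f"N{i}": {"C", "N1", "N2"} - {f"N{i}"} for i in range(1, 5)}}
        return names, positions, neighbors

    def test_constant_neighbors(self, rng):
        names, positions, neighbors = self._square_setup()
        trials = [rng.normal(size=(5, 40)) for _ in range(10)]
        for t in trials:
            t[1:] = 5.0
        epochs = make_epochs(trials, names=names)
        rep = tukey_outlier_screen(epochs, motor_channels=())
        rep.bad[:] = False
        rep.bad[2, 0] = True
        rep.decisions[2] = "interpolate"
        out = interpolate_bad_channels(epochs, rep, neighbors, positions)
        assert np.allclose(out.trials[2][0], 5.0)

    def test_two_equidistant_neighbors_average(self, rng):
        names, positions, neighbors = self._square_setup()
        trials = [rng.normal(size=(5, 20)) for _ in range(10)]
        for t in trials:
            t[1] = 0.0  # N1
            t[2] = 10.0  # N2
        epochs = make_epochs(trials, names=names)
        rep = tukey_outlier_screen(epochs, motor_channels=())
        rep.bad[:] = False
        rep.bad[0, 0] = True
        rep.bad[0, 3] = True  # N3 also bad -> excluded from the average
        rep.bad[0, 4] = True
        rep.decisions[0] = "interpolate"
        out = interpolate_bad_channels(epochs, rep, neighbors, positions)
        assert np.allclose(out.trials[0][0], 5.0)

    def test_no_flags_identity_and_rejection_drops(self, rng):
        names, positions, neighbors = self._square_setup()
        epochs = make_epochs([rng.normal(size=(5, 20)) for _ in range(10)],
                             names=names)
        rep = tukey_outlier_screen(epochs, motor_channels=())
        rep.bad[:] = False
        rep.decisions[:] = ["keep"] * 10
        rep.decisions[7] = "reject"
        out = interpolate_bad_channels(epochs, rep, neighbors, positions)
        assert out.n_trials == 9
        assert np.array_equal(out.trials[0], epochs.trials[0])
        assert np.array_equal(out.labels, np.delete(epochs.labels, 7))

    def test_isolated_channel_error(self, rng):
        names, positions, neighbors = self._square_setup()
        epochs = make_epochs([rng.normal(size=(5, 20)) for _ in range(10)],
                             names=names)
        rep = tukey_outlier_screen(epochs, motor_channels=())
        rep.bad[:] = False
        rep.bad[0, 0] = True  # C bad too: N1 keeps only one good neighbor
        rep.bad[0, 1] = True
        rep.decisions[0] = "interpolate"
        with pytest.raises(ValueError, match="N1"):
            interpolate_bad_channels(epochs, rep, neighbors, positions)


class TestSmoothing:
    def test_constant_unchanged(self):
        epochs = make_epochs([np.full((3, 100), 2.5)], labels=[1], names=["a", "b", "c"])
        out = moving_average_smooth(epochs, 100.0)
        assert np.allclose(out.trials[0], 2.5)

    def test_impulse_response_is_21_sample_plateau(self):
        x = np.zeros((1, 201))
        x[0, 100] = 1.0
        epochs = make_epochs([x], labels=[1], names=["a"])
        out = moving_average_smooth(epochs, 100.0).trials[0][0]
        assert np.allclose(out[90:111], 1 / 21)
        assert out[89] == 0 and out[111] == 0

    def test_nyquist_alternation_suppressed(self):
        x = np.tile([1.0, -1.0], 200)[None, :]
        epochs = make_epochs([x], labels=[1], names=["a"])
        out = moving_average_smooth(epochs, 100.0).trials[0][0]
        assert np.all(np.abs(out[30:-30]) < 0.05)

    def test_commutes_with_channel_permutation(self, rng):
        trial = rng.normal(size=(6, 150))
        names = [f"c{i}" for i in range(6)]
        perm = rng.permutation(6)
        a = moving_average_smooth(make_epochs([trial], [1], names)).trials[0]
        b = moving_average_smooth(
            make_epochs([trial[perm]], [1], [names[i] for i in perm])
        ).trials[0]
        assert np.allclose(a[perm], b)

    def test_lengths_preserved(self, participant):
        out = moving_average_smooth(participant.sleep)
        for a, b in zip(out.trials, participant.sleep.trials):
            assert a.shape == b.shape
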