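import numpy as np
import pytest
from scipy import signal as sps

from drowsnet.montage import montage
from drowsnet.preprocess import (
    FIVE_CLASS,
    TWO_CLASS,
    LabelScheme,
    bandpass_filter,
    downsample,
    make_folds,
    map_labels,
    notch_filter,
    reject_eog_ics,
    segment_epochs,
)
from drowsnet.simulate import Event, RawSession, SimConfig, simulate_session


def _session_from_array(data, fs, events=()):
    return RawSession(
        data=data, channel_labels=montage()[: data.shape[0]],
        channel_types=["EEG"] * (data.shape[0] - 4) + ["EOG"] * 4,
        events=list(events), fs=fs,
    )


def _tone_session(freq, fs=200.0, seconds=60.0, n_ch=34):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return _session_from_array(data, fs)


class TestBandpass:
    def test_drift_attenuated_matches_analytic_response(self):
        """0.1 Hz content drops >= 20 dB, and the measured attenuation agrees
        with the analytic squared-magnitude response of the cascaded filter."""
        fs, f0 = 200.0, 0.1
        s = _tone_session(f0, fs=fs, seconds=120.0, n_ch=34)
        out = bandpass_filter(s)
        mid = slice(int(30 * fs), int(90 * fs))
        gain = np.sqrt(np.mean(out.data[0, mid] ** 2) / np.mean(s.data[0, mid] ** 2))
        sos = sps.butter(2, [1.0, 50.0], btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[f0], fs=fs)
        oracle_gain = np.abs(h[0]) ** 2  # forward-backward squares the magnitude
        assert 20 * np.log10(gain) < -20
        assert gain == pytest.approx(oracle_gain, rel=0.2)

    def test_zero_phase_at_10hz(self):
        fs = 200.0
        s = _tone_session(10.0, fs=fs, seconds=30.0, n_ch=34)
        out = bandpass_filter(s)
        mid = slice(int(5 * fs), int(25 * fs))
        a, b = s.data[0, mid], out.data[0, mid]
        xc = np.correlate(a - a.mean(), b - b.mean(), mode="full")
        lag = np.argmax(xc) - (len(a) - 1)
        assert lag == 0

    def test_zero_input_zero_output(self):
        s = _session_from_array(np.zeros((34, 4000)), 200.0)
        assert np.allclose(bandpass_filter(s).data, 0.0)

    def test_high_above_nyquist_raises(self):
        s = _session_from_array(np.zeros((34, 1000)), 90.0 + 12.0)  # 102 Hz
        with pytest.raises(ValueError):
            bandpass_filter(s, high=51.0 + 1.0)

    def test_time_reversal_symmetry(self, rng):
        """Zero-phase: filtering the reversed signal and reversing equals
        filtering the signal."""
        data = rng.standard_normal((34, 4000))
        s = _session_from_array(data, 200.0)
        fwd = bandpass_filter(s).data
        rev = bandpass_filter(_session_from_array(data[:, ::-1].copy(), 200.0)).data[:, ::-1]
        rel = np.sqrt(np.mean((fwd - rev) ** 2) / np.mean(fwd**2))
        assert rel < 1e-6


class TestNotch:
    def test_60hz_suppressed(self):
        fs = 200.0
        s = _tone_session(60.0, fs=fs, seconds=30.0)
        out = notch_filter(s)
        mid = slice(int(5 * fs), int(25 * fs))
        ratio = np.sqrt(np.mean(out.data[0, mid] ** 2) / np.mean(s.data[0, mid] ** 2))
        assert ratio < 0.1
        b, a = sps.iirnotch(60.0, 30.0, fs=fs)
        _, h = sps.freqz(b, a, worN=[60.0], fs=fs)
        assert ratio == pytest.approx(np.abs(h[0]) ** 2, abs=0.02)

    def test_10hz_preserved(self):
        fs = 200.0
        s = _tone_session(10.0, fs=fs, seconds=30.0)
        out = notch_filter(s)
        mid = slice(int(5 * fs), int(25 * fs))
        ratio = np.sqrt(np.mean(out.data[0, mid] ** 2) / np.mean(s.data[0, mid] ** 2))
        assert abs(ratio - 1.0) < 0.05

    def test_zero_io(self):
        s = _session_from_array(np.zeros((34, 1000)), 200.0)
        assert np.allclose(notch_filter(s).data, 0.0)

    def test_above_nyquist_raises(self):
        s = _session_from_array(np.zeros((34, 1000)), 110.0)
        with pytest.raises(ValueError):
            notch_filter(s, f0=60.0)


class TestDownsample:
    def test_length_and_rate(self):
        s = _session_from_array(np.zeros((34, 60_000)), 1000.0)
        out = downsample(s, 100.0)
        assert out.fs == 100.0
        assert out.data.shape[1] == 6000

    def test_event_rescaling(self):
        s = _session_from_array(np.zeros((34, 20_000)), 1000.0,
                                events=[Event(10_000, "trial_start")])
        out = downsample(s, 100.0)
        assert out.events[0].sample == 1000

    def test_sinusoid_amplitude_preserved(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        data = np.tile(np.sin(2 * np.pi * 5.0 * t), (34, 1))
        out = downsample(_session_from_array(data, fs), 100.0)
        # oracle: the same 5 Hz sinusoid evaluated on the 100 Hz clock
        expected = np.sin(2 * np.pi * 5.0 * np.arange(1000) / 100.0)
        assert np.max(np.abs(out.data[0] - expected)) < 0.01

    def test_non_integer_factor_raises(self):
        s = _session_from_array(np.zeros((34, 1000)), 250.0)
        with pytest.raises(ValueError):
            downsample(s, 100.0)


@pytest.fixture(scope="module")
def blinky_session():
    cfg = SimConfig(n_trials=3, trial_flight_s=6.0, kss_window_s=2.0, fs=200.0,
                    blink_rate=40.0, blink_amp=400.0, seed=21)
    return downsample(bandpass_filter(simulate_session(cfg)), 100.0)


@pytest.fixture(scope="module")
def clean_session():
    cfg = SimConfig(n_trials=3, trial_flight_s=6.0, kss_window_s=2.0, fs=200.0,
                    blink_rate=0.0, seed=22)
    return downsample(bandpass_filter(simulate_session(cfg)), 100.0)


class TestRejectEogIcs:
    def test_nothing_to_reject_is_near_lossless(self, clean_session):
        out = reject_eog_ics(clean_session, threshold=0.7, seed=0)
        eeg = clean_session.eeg_indices()
        rel = np.sqrt(np.mean((out.data[eeg] - clean_session.data[eeg]) ** 2)
                      / np.mean(clean_session.data[eeg] ** 2))
        assert rel < 0.01

    def test_blink_correlation_reduced(self, blinky_session):
        out = reject_eog_ics(blinky_session, threshold=0.7, seed=0)
        fp1 = blinky_session.channel_labels.index("Fp1")
        eog1 = blinky_session.channel_labels.index("EOG1")
        before = abs(np.corrcoef(blinky_session.data[fp1], blinky_session.data[eog1])[0, 1])
        after = abs(np.corrcoef(out.data[fp1], out.data[eog1])[0, 1])
        assert after < before

    def test_zero_threshold_rejects_everything(self, clean_session):
        out = reject_eog_ics(clean_session, threshold=0.0, seed=0)
        eeg = clean_session.eeg_indices()
        rel = np.sqrt(np.mean(out.data[eeg] ** 2) / np.mean(clean_session.data[eeg] ** 2))
        assert rel < 0.01

    def test_eog_channels_pass_through(self, blinky_session):
        out = reject_eog_ics(blinky_session, threshold=0.7, seed=0)
        eog = blinky_session.eog_indices()
        assert np.array_equal(out.data[eog], blinky_session.data[eog])

    def test_nonconvergence_raise_mode(self, clean_session):
        with pytest.raises(RuntimeError, match="ICA did not converge"):
            reject_eog_ics(clean_session, threshold=0.7, seed=0, max_iter=3,
                           tol=1e-12, on_nonconvergence="raise")

    def test_invalid_nonconvergence_mode(self, clean_session):
        with pytest.raises(ValueError):
            reject_eog_ics(clean_session, on_nonconvergence="ignore")


class TestSegmentEpochs:
    def test_counts_and_geometry(self, short_epochs):
        # 6 trials x 6 flight seconds -> 36 one-second epochs of 30 x 100
        assert short_epochs.epochs.shape == (36, 30, 100)
        assert np.all(np.bincount(short_epochs.trial_index) == 6)

    def test_single_trial_constant_kss(self):
        cfg = SimConfig(n_trials=1, trial_flight_s=4.0, kss_window_s=2.0, fs=200.0,
                        kss_sequence=[4], miss_prob=0.0, seed=0)
        s = downsample(bandpass_filter(simulate_session(cfg)), 100.0)
        es = segment_epochs(s, trial_flight_s=4.0, kss_window_s=2.0)
        assert len(es) == 4
        assert np.all(es.kss == 4)

    def test_short_trial_raises_naming_trial(self):
        cfg = SimConfig(n_trials=2, trial_flight_s=4.0, kss_window_s=2.0, fs=200.0, seed=0)
        s = simulate_session(cfg)
        truncated = s.copy_with(data=s.data[:, : s.n_samples - 500])
        with pytest.raises(ValueError, match="trial 1"):
            segment_epochs(truncated, trial_flight_s=4.0, kss_window_s=2.0)

    def test_kss_window_excluded(self, short_session, short_epochs):
        # flight takes 6 of every 8 seconds; epochs only cover the flight part
        total_seconds = short_session.n_samples / short_session.fs
        assert len(short_epochs) == int(total_seconds * 6 / 8)


class TestMapLabels:
    @pytest.mark.parametrize("kss,expected", [(1, 0), (6, 0), (7, 1), (9, 1)])
    def test_two_class(self, kss, expected):
        assert map_labels(kss, TWO_CLASS) == expected

    @pytest.mark.parametrize("kss,expected",
                             [(1, 0), (2, 0), (3, 1), (4, 1), (5, 2), (6, 2), (7, 3), (8, 3), (9, 4)])
    def test_five_class(self, kss, expected):
        assert map_labels(kss, FIVE_CLASS) == expected

    @pytest.mark.parametrize("bad", [0, 10, -3])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValueError):
            map_labels(bad, TWO_CLASS)

    def test_vectorized(self):
        out = map_labels(np.array([1, 6, 7, 9]), TWO_CLASS)
        assert np.array_equal(out, [0, 0, 1, 1])

    def test_scheme_must_partition(self):
        with pytest.raises(ValueError):
            LabelScheme(mode="bad", class_names=("a", "b"), mapping=((1, 5), (7, 9)))


class TestMakeFolds:
    def test_quarter_per_trial(self):
        cfg = SimConfig(n_trials=2, trial_flight_s=60.0, kss_window_s=2.0, fs=200.0, seed=0)
        s = downsample(bandpass_filter(simulate_session(cfg)), 100.0)
        es = segment_epochs(s, trial_flight_s=60.0, kss_window_s=2.0)
        folds = make_folds(es, k=4, seed=0)
        for fold in range(4):
            for trial in (0, 1):
                n = np.sum((folds.fold_ids == fold) & (es.trial_index == trial))
                assert n == 15  # 60 epochs/trial, k=4

    def test_partition_property(self, short_epochs):
        folds = make_folds(short_epochs, k=3, seed=1)
        assert np.all(folds.fold_ids >= 0) and np.all(folds.fold_ids < 3)
        total = sum(folds.test_mask(f).sum() for f in range(3))
        assert total == len(short_epochs)
        for f in range(3):
            for g in range(f + 1, 3):
                assert not np.any(folds.test_mask(f) & folds.test_mask(g))

    def test_seed_determinism(self, short_epochs):
        a = make_folds(short_epochs, k=3, seed=7)
        b = make_folds(short_epochs, k=3, seed=7)
        c = make_folds(short_epochs, k=3, seed=8)
        assert np.array_equal(a.fold_ids, b.fold_ids)
        assert not np.array_equal(a.fold_ids, c.fold_ids)

    def test_trial_granularity_subject_disjoint_trials(self, short_epochs):
        folds = make_folds(short_epochs, k=3, seed=0, granularity="trial")
        for f in range(3):
            test_trials = set(short_epochs.trial_index[folds.test_mask(f)])
            train_trials = set(short_epochs.trial_index[folds.train_mask(f)])
            assert not test_trials & train_trials

    def test_too_few_epochs_per_trial_raises(self, short_epochs):
        with pytest.raises(ValueError):
            make_folds(short_epochs, k=10, seed=0)
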