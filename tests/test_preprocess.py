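"""Preprocessing chain: crop, interpolation, filters, windows, rejection."""

import numpy as np
import pytest
from scipy import signal as sp_signal

import eegage as E
from eegage.containers import Hypnogram, Recording
from eegage.preprocess import TooShortError, preprocess_recording

FS = 256.0
CH = ["TP9", "Fp1", "Fp2", "TP10"]


def make_rec(signal, modality="meditation", sfreq=FS, hyp=None):
    return Recording(signal=signal, sfreq=sfreq, channel_names=CH[: signal.shape[0]],
                     modality=modality, hypnogram=hyp)


def tone(freq, seconds, sfreq=FS, n_ch=4):
    t = np.arange(int(seconds * sfreq)) / sfreq
    return np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))


def band_db(before, after, freq, sfreq=FS):
    """Attenuation (dB) in a narrow band around ``freq``."""
    f, pb = sp_signal.welch(before[0], sfreq, nperseg=8192)
    f, pa = sp_signal.welch(after[0], sfreq, nperseg=8192)
    sel = (f > freq - 0.4) & (f < freq + 0.4)
    return 10 * np.log10(pa[sel].sum() / pb[sel].sum())


class TestCrop:
    @pytest.mark.parametrize(
        "minutes,expected_seconds", [(14, 480.0), (5, 240.0)]
    )
    def test_keep_at_most_eight_minutes_after_first(self, minutes, expected_seconds):
        rec = make_rec(np.random.default_rng(0).standard_normal((4, int(minutes * 60 * FS))))
        out = E.crop_meditation(rec)
        assert out.duration == pytest.approx(expected_seconds)
        # output starts 60 s into the input
        np.testing.assert_array_equal(out.signal[:, 0], rec.signal[:, int(60 * FS)])

    def test_boundary_one_second(self):
        rec = make_rec(np.zeros((4, int(61 * FS))))
        assert E.crop_meditation(rec).duration == pytest.approx(1.0)

    def test_too_short_raises(self):
        with pytest.raises(TooShortError):
            E.crop_meditation(make_rec(np.zeros((4, int(60 * FS)))))


class TestInterpolation:
    def test_linear_midpoint(self):
        sig = np.tile([1.0, np.nan, 3.0], (4, 1))
        out = E.interpolate_missing(make_rec(sig))
        np.testing.assert_allclose(out.signal, np.tile([1.0, 2.0, 3.0], (4, 1)))

    def test_identity_when_complete(self):
        sig = np.random.default_rng(1).standard_normal((4, 100))
        out = E.interpolate_missing(make_rec(sig.copy()))
        np.testing.assert_array_equal(out.signal, sig)

    def test_interior_gap_closed_form(self):
        sig = np.tile([0.0, np.nan, np.nan, np.nan, 4.0], (4, 1))
        out = E.interpolate_missing(make_rec(sig))
        np.testing.assert_allclose(out.signal[0], [0, 1, 2, 3, 4])

    def test_edges_extend_nearest(self):
        sig = np.tile([np.nan, 5.0, 6.0, np.nan], (4, 1))
        out = E.interpolate_missing(make_rec(sig))
        np.testing.assert_allclose(out.signal[0], [5, 5, 6, 6])

    def test_fully_missing_channel(self):
        sig = np.ones((4, 50))
        sig[2] = np.nan
        with pytest.raises(ValueError, match="fully missing"):
            E.interpolate_missing(make_rec(sig))


class TestFilters:
    def test_drift_attenuated(self):
        rec = make_rec(tone(0.01, 120))
        out = E.bandpass_filter(rec)
        power_ratio = (out.signal[0] ** 2).mean() / (rec.signal[0] ** 2).mean()
        assert 10 * np.log10(power_ratio) <= -20

    def test_passband_tone_preserved(self):
        rec = make_rec(tone(10.0, 120))
        out = E.bandpass_filter(rec)
        mid = slice(int(20 * FS), int(100 * FS))
        ratio = out.signal[0, mid].std() / rec.signal[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_zero_in_zero_out(self):
        out = E.bandpass_filter(make_rec(np.zeros((4, 1000))))
        np.testing.assert_array_equal(out.signal, 0.0)

    def test_zero_phase_peak_latency(self):
        sig = np.zeros((4, int(20 * FS)))
        sig[:, int(10 * FS)] = 1.0
        out = E.bandpass_filter(make_rec(sig), 1.0, 30.0)
        assert abs(int(np.argmax(out.signal[0])) - int(10 * FS)) <= 1

    def test_invalid_band_edges(self):
        with pytest.raises(ValueError):
            E.bandpass_filter(make_rec(np.zeros((4, 1000))), 49.0, 0.1)

    @pytest.mark.parametrize("freq", [21.3, 50.0])
    def test_notch_attenuates_targets(self, freq):
        rec = make_rec(tone(freq, 60))
        assert band_db(rec.signal, E.notch_filter(rec).signal, freq) <= -20

    def test_notch_spares_neighbours(self):
        rec = make_rec(tone(10.0, 60))
        assert abs(band_db(rec.signal, E.notch_filter(rec).signal, 10.0)) < 3

    def test_notch_default_list(self):
        assert E.NOTCH_FREQS == (16.0, 21.3, 32.0, 42.7, 50.0, 60.0)

    def test_notch_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            E.notch_filter(make_rec(np.zeros((4, 1000))), freqs=(200.0,))


class TestWindows:
    def test_sleep_window_count(self):
        hyp = Hypnogram(labels=("N2",) * 10)
        rec = make_rec(np.zeros((4, int(300 * FS))), modality="sleep", hyp=hyp)
        ws = E.make_windows(rec)
        assert ws.n_windows == 10
        assert ws.window_length == 30.0
        assert list(ws.stages) == ["N2"] * 10

    def test_meditation_window_count(self):
        ws = E.make_windows(make_rec(np.zeros((4, int(480 * FS)))))
        assert ws.n_windows == 48 and ws.window_length == 10.0

    def test_trailing_remainder_dropped(self):
        ws = E.make_windows(make_rec(np.zeros((4, int(95 * FS)))), length=30.0)
        assert ws.n_windows == 3

    def test_windows_contiguous_in_source_order(self):
        sig = np.arange(4 * int(30 * FS), dtype=float).reshape(4, -1)
        ws = E.make_windows(make_rec(sig), length=10.0)
        flat = ws.windows.transpose(1, 0, 2).reshape(4, -1)
        np.testing.assert_array_equal(flat, sig)

    def test_too_short(self):
        with pytest.raises(TooShortError):
            E.make_windows(make_rec(np.zeros((4, 100))), length=10.0)


class TestRejection:
    def test_single_channel_spike_rejects(self):
        wins = np.zeros((1, 4, 100))
        wins[0, 2, 50] = 300.0
        ws = E.WindowSet(windows=wins, sfreq=FS, window_length=100 / FS)
        assert E.reject_ptp(ws).retained.tolist() == [False]

    def test_all_zero_retained(self):
        ws = E.WindowSet(windows=np.zeros((5, 4, 100)), sfreq=FS, window_length=100 / FS)
        assert E.reject_ptp(ws).retained.all()

    def test_planted_artifacts_counted_exactly(self):
        rng = np.random.default_rng(2)
        wins = rng.normal(0, 10, (10, 4, 100))
        planted = [1, 4, 7]
        for k in planted:
            wins[k, rng.integers(0, 4), 50] += 400.0
        ws = E.reject_ptp(E.WindowSet(windows=wins, sfreq=FS, window_length=100 / FS))
        assert ws.n_retained == 10 - len(planted)
        assert (~ws.retained[planted]).all()

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        wins = rng.normal(0, 120, (8, 4, 100))
        once = E.reject_ptp(E.WindowSet(windows=wins, sfreq=FS, window_length=100 / FS))
        twice = E.reject_ptp(once)
        np.testing.assert_array_equal(once.retained, twice.retained)


class TestResample:
    def test_sample_count(self):
        ws = E.WindowSet(windows=np.zeros((3, 4, int(30 * FS))), sfreq=FS, window_length=30.0)
        out = E.resample(ws, 128.0)
        assert out.windows.shape[-1] == 3840 and out.sfreq == 128.0

    def test_tone_amplitude_preserved(self):
        wins = tone(10.0, 10)[None, ...]
        ws = E.WindowSet(windows=wins, sfreq=FS, window_length=10.0)
        out = E.resample(ws, 128.0)
        assert out.windows[0, 0].std() == pytest.approx(wins[0, 0].std(), rel=0.02)

    def test_identity_rate(self):
        ws = E.WindowSet(windows=np.ones((2, 4, 256)), sfreq=FS, window_length=1.0)
        np.testing.assert_array_equal(E.resample(ws, FS).windows, ws.windows)

    def test_aliasing_rate_rejected(self):
        ws = E.WindowSet(windows=np.zeros((2, 4, 2560)), sfreq=FS, window_length=10.0)
        with pytest.raises(ValueError, match="alias"):
            E.resample(ws, 64.0)


class TestFullChain:
    def test_generated_recordings_pass_preprocessing(self):
        """Generator + pipeline closure, including dropouts and artifacts."""
        cfg = E.GeneratorConfig(n_subjects=1, duration=180.0, seed=6,
                                dropout_rate=0.01, artifact_rate=8.0)
        rec = E.synthesize_recording({"subject_id": "sub-0000", "age": 33.0}, None, cfg, seed=1)
        ws = preprocess_recording(rec)
        assert ws.sfreq == 128.0
        assert ws.n_windows == 12  # (180 - 60) s / 10 s
        assert np.isfinite(ws.windows).all()
        # heavy artifact load must reject at least one window
        assert ws.n_retained < ws.n_windows

    def test_retained_windows_respect_threshold(self):
        cfg = E.GeneratorConfig(n_subjects=1, duration=180.0, seed=7, artifact_rate=5.0)
        rec = E.synthesize_recording({"subject_id": "sub-0000", "age": 50.0}, None, cfg, seed=2)
        ws = preprocess_recording(rec)
        kept = ws.windows[ws.retained]
        # rejection ran before resampling; resampling can only shrink ptp slightly
        ptp = kept.max(axis=-1) - kept.min(axis=-1)
        assert ptp.max() <= 260.0
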