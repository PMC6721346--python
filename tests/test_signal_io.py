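import numpy as np
import pytest

from mientropic import (
    EEGRecording,
    SynthConfig,
    bandpass_filter,
    epoch_trials,
    generate_dataset,
    load_recording,
    load_trialset,
    save_trialset,
)
from conftest import band_power_fraction


def _write(tmp_path, text, name="rec.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadRecording:
    def test_three_column_file(self, tmp_path, rng):
        data = rng.standard_normal((100, 3))
        p = _write(tmp_path, "\n".join(",".join(f"{v:.6f}" for v in row) for row in data))
        rec = load_recording(p, fs=250, channel_labels=["C3", "Cz", "C4"])
        assert rec.n_channels == 3
        assert rec.n_samples == 100
        np.testing.assert_allclose(rec.channel("Cz"), data[:, 1], atol=1e-6)

    def test_tab_delimited_autodetect(self, tmp_path):
        p = _write(tmp_path, "1.0\t2.0\n3.0\t4.0\n")
        rec = load_recording(p, fs=100, channel_labels=["a", "b"])
        np.testing.assert_array_equal(rec.samples, [[1, 3], [2, 4]])

    def test_empty_file_errors(self, tmp_path):
        p = _write(tmp_path, "")
        with pytest.raises(ValueError, match="no samples"):
            load_recording(p, fs=250, channel_labels=["C3"])

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_recording(tmp_path / "absent.csv", fs=250, channel_labels=["C3"])

    def test_non_numeric_cell_errors(self, tmp_path):
        p = _write(tmp_path, "1.0,2.0\nx,4.0\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_recording(p, fs=250, channel_labels=["C3", "C4"])

    def test_column_count_mismatch_errors(self, tmp_path):
        p = _write(tmp_path, "1.0,2.0\n3.0,4.0\n")
        with pytest.raises(ValueError, match="columns"):
            load_recording(p, fs=250, channel_labels=["C3", "Cz", "C4"])

    def test_non_finite_values_rejected(self, tmp_path):
        p = _write(tmp_path, "1.0,2.0\nnan,4.0\n")
        with pytest.raises(ValueError, match="non-finite"):
            load_recording(p, fs=250, channel_labels=["C3", "C4"])


def test_trialset_roundtrip_full_precision(tmp_path):
    trials = generate_dataset(SynthConfig(n_trials_per_class=2, trial_length=400, seed=3))
    save_trialset(trials, tmp_path / "out")
    back = load_trialset(tmp_path / "out")
    assert back.labels == trials.labels
    assert back.trials[0].channel_labels == ["C3", "C4"]
    for a, b in zip(trials.trials, back.trials):
        np.testing.assert_array_equal(a.samples, b.samples)


class TestBandpass:
    def test_default_band_is_8_32(self):
        import inspect

        sig = inspect.signature(bandpass_filter)
        assert sig.parameters["low"].default == 8.0
        assert sig.parameters["high"].default == 32.0

    def test_passband_tone_preserved(self):
        t = np.arange(2000) / 250.0
        rec = EEGRecording(np.sin(2 * np.pi * 20 * t), fs=250)
        out = bandpass_filter(rec)
        assert out.n_samples == rec.n_samples
        p_in = band_power_fraction(rec.samples[0], 250, 19, 21) * np.sum(rec.samples**2)
        p_out = band_power_fraction(out.samples[0], 250, 19, 21) * np.sum(out.samples**2)
        assert abs(p_out - p_in) / p_in < 0.05

    def test_stopband_tone_attenuated_20db(self):
        t = np.arange(2000) / 250.0
        rec = EEGRecording(np.sin(2 * np.pi * 2 * t), fs=250)
        out = bandpass_filter(rec)
        atten = 10 * np.log10(np.sum(rec.samples**2) / np.sum(out.samples**2))
        assert atten >= 20

    def test_passband_idempotent_within_5pct(self, rng):
        # 10-20 Hz band-limited noise: refiltering changes power < 5%
        x = rng.standard_normal(4000)
        rec = bandpass_filter(EEGRecording(x, fs=250), 10, 20)
        again = bandpass_filter(rec)
        p0, p1 = np.sum(rec.samples**2), np.sum(again.samples**2)
        assert abs(p1 - p0) / p0 < 0.05

    def test_band_outside_nyquist_errors(self):
        rec = EEGRecording(np.zeros(100) + np.arange(100), fs=100)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, 8, 60)


class TestEpochTrials:
    def test_two_trials(self):
        rec = EEGRecording(np.arange(4000.0), fs=250)
        ts = epoch_trials(rec, [0, 2000], ["left", "right"], length=2000)
        assert len(ts) == 2
        assert ts.trial_length == 2000
        np.testing.assert_array_equal(ts.trials[1].samples[0], np.arange(2000.0, 4000.0))

    def test_out_of_range_onset_names_trial(self):
        rec = EEGRecording(np.arange(4000.0), fs=250)
        with pytest.raises(ValueError, match="trial 1"):
            epoch_trials(rec, [0, 3000], ["left", "right"], length=2000)

    def test_wrong_label_count_errors(self):
        rec = EEGRecording(np.arange(4000.0), fs=250)
        with pytest.raises(ValueError, match="labels"):
            epoch_trials(rec, [0, 2000], ["left"], length=2000)
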