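"""Bad-channel screening, filters, referencing, Morlet power, segmentation."""

import numpy as np
import pandas as pd
import pytest

from ndrms import (
    Recording,
    UNFILTERED,
    bandpass_filter,
    common_median_reference,
    default_bandset,
    detect_bad_channels,
    morlet_band_power,
    notch_filter,
    segment_trials,
)

FS = 2000.0


def _rec(data, fs=FS, good=None):
    data = np.asarray(data, dtype=float)
    return Recording(data, fs, tuple(f"ch{i}" for i in range(len(data))), good)


def _sine(freq, dur=2.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestBadChannels:
    def test_constant_channel_flagged_flat(self, rng):
        data = rng.standard_normal((4, 4000))
        data[2] = 3.14
        good, reasons = detect_bad_channels(_rec(data))
        assert not good[2] and reasons["ch2"] == ["flat"]
        assert good[[0, 1, 3]].all()

    def test_scaled_channel_flagged_amplitude(self, rng):
        data = rng.standard_normal((8, 4000))
        data[5] *= 100.0
        good, reasons = detect_bad_channels(_rec(data))
        assert "amplitude" in reasons["ch5"]
        assert good.sum() == 7

    def test_pure_mains_flagged_line_noise(self, rng):
        data = rng.standard_normal((4, 8000)) * 0.1
        data[1] = _sine(50.0, dur=4.0)  # line power ratio ~1 > 0.5
        good, reasons = detect_bad_channels(_rec(data))
        assert "line_noise" in reasons["ch1"]

    def test_spiky_channel_flagged_outliers(self, rng):
        data = rng.standard_normal((6, 4000))
        spikes = rng.choice(4000, size=80, replace=False)  # 2% of samples
        data[3, spikes] += 40.0
        good, reasons = detect_bad_channels(_rec(data))
        assert "outliers" in reasons["ch3"]

    def test_clean_data_all_good(self, rng):
        good, reasons = detect_bad_channels(_rec(rng.standard_normal((6, 4000))))
        assert good.all() and reasons == {}


class TestNotch:
    def test_mains_attenuated(self):
        rec = _rec([_sine(50.0)])
        out = notch_filter(rec)
        assert rms(out.data[0]) < 0.05 * rms(rec.data[0])

    def test_passband_preserved(self):
        rec = _rec([_sine(10.0)])
        out = notch_filter(rec)
        assert rms(out.data[0]) > 0.95 * rms(rec.data[0])

    def test_harmonics_of_24_all_notched(self):
        # harmonics 24, 48, ..., 480: 20 stop bands below the 499 Hz ceiling
        assert len([k for k in range(1, 100) if 24 * k <= 499]) == 20
        rec = _rec([_sine(48.0, dur=6.0) + _sine(240.0, dur=6.0)])
        out = notch_filter(rec, base_freqs_hz=(24.0,))
        interior = slice(2000, -2000)  # narrow stop bands ring at the edges
        assert rms(out.data[0, interior]) < 0.05 * rms(rec.data[0, interior])

    def test_stopband_at_nyquist_errors(self):
        rec = _rec([_sine(10.0)], fs=400.0)
        with pytest.raises(ValueError):
            notch_filter(rec, base_freqs_hz=(50.0,), max_freq_hz=300.0)

    def test_linearity(self, rng):
        x = rng.standard_normal((2, 4000))
        a = notch_filter(_rec(3.5 * x)).data
        b = 3.5 * notch_filter(_rec(x)).data
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestCommonMedianReference:
    def test_worked_example(self):
        rec = _rec([[1, 1], [2, 3], [10, 10]], fs=10.0)
        out = common_median_reference(rec)
        np.testing.assert_allclose(out.data, [[-1, -2], [0, 0], [8, 7]])

    def test_identical_channels_zeroed(self):
        rec = _rec(np.tile(np.arange(5.0), (3, 1)), fs=10.0)
        assert np.all(common_median_reference(rec).data == 0)

    def test_median_of_output_is_zero(self, rng):
        out = common_median_reference(_rec(rng.standard_normal((5, 100)), fs=10.0))
        np.testing.assert_allclose(np.median(out.data, axis=0), 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        rec = _rec(rng.standard_normal((5, 200)), fs=10.0)
        once = common_median_reference(rec)
        twice = common_median_reference(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_bad_channels_untouched(self, rng):
        data = rng.standard_normal((4, 50))
        good = np.array([True, True, True, False])
        out = common_median_reference(_rec(data, fs=10.0, good=good))
        np.testing.assert_array_equal(out.data[3], data[3])

    def test_too_few_good_channels(self, rng):
        rec = _rec(rng.standard_normal((3, 50)), fs=10.0,
                   good=np.array([True, False, False]))
        with pytest.raises(ValueError):
            common_median_reference(rec)


class TestBandpass:
    def test_unfiltered_sentinel_identity(self, rng):
        rec = _rec(rng.standard_normal((2, 1000)))
        np.testing.assert_array_equal(bandpass_filter(rec, UNFILTERED).data, rec.data)

    def test_inband_tone_preserved(self):
        rec = _rec([_sine(100.0)])
        assert rms(bandpass_filter(rec, (64, 128)).data) > 0.9 * rms(rec.data)

    def test_out_of_band_tone_rejected(self):
        rec = _rec([_sine(100.0, dur=4.0)])
        out = bandpass_filter(rec, (1, 4)).data[:, 2000:-2000]
        assert rms(out) < 0.01 * rms(rec.data[:, 2000:-2000])

    def test_default_bandset_shape(self):
        bands = default_bandset()
        assert len(bands) == 9 and bands[-1] == UNFILTERED
        assert bands[0] == (1, 4) and bands[-2] == (256, 499)

    def test_invalid_band_errors(self):
        with pytest.raises(ValueError):
            bandpass_filter(_rec([_sine(10.0)]), (100, 50))


class TestMorletPower:
    def test_tone_at_band_center_flat_power(self):
        x = _sine(90.0, dur=4.0)
        p = morlet_band_power(np.array([x]), (64, 128), fs_hz=FS)[0]
        inner = p[2000:-2000]  # away from edges
        assert np.std(inner) / np.mean(inner) < 0.1

    def test_zero_signal_zero_power(self):
        p = morlet_band_power(np.zeros((1, 4000)), (64, 128), fs_hz=FS)
        assert np.allclose(p, 0.0)

    def test_quadratic_amplitude_scaling(self):
        x = np.array([_sine(90.0, dur=2.0)])
        p1 = morlet_band_power(x, (64, 128), fs_hz=FS)
        p2 = morlet_band_power(2 * x, (64, 128), fs_hz=FS)
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-9)

    def test_epoch_too_short_errors(self):
        with pytest.raises(ValueError):
            morlet_band_power(np.zeros((1, 100)), (1, 4), fs_hz=FS)


class TestSegmentation:
    def _events(self, onsets):
        return pd.DataFrame({"onset": onsets, "duration": 0.0, "trial_type": "stimulus"})

    def test_half_isi_windows(self, rng):
        rec = _rec(rng.standard_normal((2, int(20 * FS))))
        trials = segment_trials(rec, self._events([10.0, 13.0, 16.0]), "half_isi")
        rest = trials.select("rest")
        # isi 3 s -> rest [8.5, 10) etc., 1.5 s windows
        assert rest.onset_s[0] == pytest.approx(8.5)
        assert rest.duration_s[0] == pytest.approx(1.5)
        assert trials.epochs.shape[-1] == int(1.5 * FS)

    def test_fixed_scheme_windows(self, rng):
        rec = _rec(rng.standard_normal((2, int(20 * FS))))
        trials = segment_trials(rec, self._events([10.0]), "fixed_1p5s")
        assert trials.select("rest").onset_s[0] == pytest.approx(8.5)
        assert trials.select("active").onset_s[0] == pytest.approx(10.0)

    def test_out_of_bounds_trial_dropped(self, rng):
        rec = _rec(rng.standard_normal((2, int(2 * FS))))
        trials = segment_trials(rec, self._events([0.2]), "fixed_1p5s")
        # rest window would start before 0: only the active trial survives
        assert trials.n_trials == 1 and trials.label[0] == "active"

    def test_sample_counts_exact(self, rng):
        rec = _rec(rng.standard_normal((2, int(30 * FS))))
        trials = segment_trials(rec, self._events([10, 12, 14, 16]), "half_isi")
        assert trials.epochs.shape[-1] == int(trials.duration_s[0] * FS)

    def test_epochs_match_recording_content(self, rng):
        rec = _rec(rng.standard_normal((2, int(20 * FS))))
        trials = segment_trials(rec, self._events([10.0]), "fixed_1p5s")
        active = trials.select("active")
        i0 = int(10.0 * FS)
        np.testing.assert_array_equal(
            active.epochs[0], rec.data[:, i0 : i0 + int(1.5 * FS)]
        )

    def test_no_valid_trials_errors(self, rng):
        rec = _rec(rng.standard_normal((2, 100)))
        with pytest.raises(ValueError):
            segment_trials(rec, self._events([50.0]), "fixed_1p5s")
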