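"""Preprocessing chain: referencing, filtering, resampling, windowing."""

import numpy as np
import pytest

from spikewav import (
    EEGRecording,
    PreprocConfig,
    bandpass_chebyshev2,
    extract_band,
    make_montage,
    normalize_trial,
    preprocess_chain,
    rereference_average,
    resample_to,
    segment_windows,
)
from spikewav.preprocess import with_window


def make_rec(data, fs=128.0, trials=None):
    n_ch, n = data.shape
    montage = make_montage({8: 8, 32: 32}.get(n_ch, 8))
    if montage.n_channels != n_ch:
        raise AssertionError("test data must use 8 or 32 channels")
    return EEGRecording(data, fs, montage, trials or [(0, n, 0)])


def tone(freq, fs, seconds, n_ch=8):
    t = np.arange(int(fs * seconds)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))


class TestRereference:
    def test_removes_channel_offsets(self, rng):
        data = rng.normal(size=(8, 100)) + np.arange(8)[:, None]
        out = rereference_average(make_rec(data))
        np.testing.assert_allclose(out.data.sum(axis=0), 0.0, atol=1e-10)

    def test_idempotent(self, rng):
        rec = make_rec(rng.normal(size=(8, 50)))
        once = rereference_average(rec)
        twice = rereference_average(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_single_channel_rejected(self, montage8):
        rec = EEGRecording(np.zeros((8, 10)), 128.0, montage8, [])
        rec.data = rec.data[:1]
        with pytest.raises(ValueError):
            rereference_average(rec)


class TestBandpass:
    CFG = PreprocConfig()

    def test_passband_tone_preserved(self):
        rec = make_rec(tone(10, 256, 4), fs=256.0)
        out = bandpass_chebyshev2(rec, self.CFG)
        mid = slice(256, -256)  # skip filter edges
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_tone_attenuated_40db(self):
        rec = make_rec(tone(60, 256, 4), fs=256.0)
        out = bandpass_chebyshev2(rec, self.CFG)
        mid = slice(256, -256)
        atten_db = 20 * np.log10(rec.data[0, mid].std() / out.data[0, mid].std())
        assert atten_db >= 40

    def test_dc_offset_removed(self):
        rec = make_rec(np.full((8, 1024), 7.0), fs=256.0)
        out = bandpass_chebyshev2(rec, self.CFG)
        assert np.abs(out.data[:, 256:-256]).max() < 0.1

    def test_band_above_nyquist_rejected(self):
        rec = make_rec(tone(10, 50, 4), fs=50.0)
        with pytest.raises(ValueError):
            bandpass_chebyshev2(rec, self.CFG)


class TestResample:
    def test_quarter_rate_length(self):
        rec = make_rec(tone(10, 512, 1), fs=512.0)
        out = resample_to(rec, 128.0)
        assert out.data.shape[1] == 128
        assert out.fs == 128.0

    def test_tone_preserved_through_resampling(self):
        rec = make_rec(tone(10, 512, 2), fs=512.0)
        out = resample_to(rec, 128.0)
        t = np.arange(out.data.shape[1]) / 128.0
        ref = np.sin(2 * np.pi * 10 * t)
        mid = slice(16, -16)
        r = np.corrcoef(out.data[0, mid], ref[mid])[0, 1]
        assert r > 0.99

    def test_identity_when_rates_match(self, rng):
        rec = make_rec(rng.normal(size=(8, 64)))
        out = resample_to(rec, 128.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_upsampling_rejected(self):
        rec = make_rec(np.zeros((8, 64)))
        with pytest.raises(ValueError):
            resample_to(rec, 256.0)

    def test_trial_bounds_rescaled(self):
        data = np.zeros((8, 1024))
        rec = make_rec(data, fs=512.0, trials=[(0, 512, 0), (512, 1024, 1)])
        out = resample_to(rec, 128.0)
        assert out.trials == [(0, 128, 0), (128, 256, 1)]


class TestNormalize:
    def test_zero_mean_unit_variance_per_trial(self, rng):
        data = rng.normal(5.0, 3.0, size=(8, 200))
        rec = make_rec(data, trials=[(0, 100, 0), (100, 200, 1)])
        out = normalize_trial(rec)
        for start, end, _ in out.trials:
            seg = out.data[:, start:end]
            np.testing.assert_allclose(seg.mean(axis=1), 0.0, atol=1e-6)
            np.testing.assert_allclose(seg.var(axis=1), 1.0, atol=1e-6)

    def test_idempotent(self, rng):
        rec = make_rec(rng.normal(size=(8, 128)))
        once = normalize_trial(rec)
        twice = normalize_trial(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-9)

    def test_trials_standardized_independently(self, rng):
        data = np.concatenate([rng.normal(0, 1, (8, 100)), rng.normal(0, 50, (8, 100))], axis=1)
        rec = make_rec(data, trials=[(0, 100, 0), (100, 200, 1)])
        out = normalize_trial(rec)
        assert abs(out.data[:, 100:].var() - 1.0) < 0.05

    def test_constant_channel_reported_by_name_and_trial(self, rng):
        data = rng.normal(size=(8, 100))
        data[2] = 4.2
        with pytest.raises(ValueError, match=r"T7.*trial 0"):
            normalize_trial(make_rec(data))


class TestExtractBand:
    def test_alpha_tone_preserved(self):
        rec = make_rec(tone(10, 128, 4))
        out = extract_band(rec, 8, 13)
        mid = slice(128, -128)
        assert abs(out.data[0, mid].std() / rec.data[0, mid].std() - 1) < 0.05

    def test_theta_tone_attenuated(self):
        rec = make_rec(tone(4, 128, 4))
        out = extract_band(rec, 8, 13)
        mid = slice(128, -128)
        atten_db = 20 * np.log10(rec.data[0, mid].std() / out.data[0, mid].std())
        assert atten_db >= 20

    def test_band_edges_survive(self):
        # the requested band must bound the passband, not the stopband
        for f in (8.5, 12.5):
            rec = make_rec(tone(f, 128, 4))
            out = extract_band(rec, 8, 13)
            mid = slice(128, -128)
            assert out.data[0, mid].std() / rec.data[0, mid].std() > 0.7

    def test_broadband_energy_reduced(self, rng):
        rec = make_rec(rng.normal(size=(8, 512)))
        out = extract_band(rec, 8, 13)
        assert out.data.var() < rec.data.var()

    def test_invalid_band_rejected(self):
        rec = make_rec(np.zeros((8, 64)))
        with pytest.raises(ValueError):
            extract_band(rec, 13, 8)


class TestSegmentation:
    def test_six_minute_trial_gives_360_one_second_windows(self):
        n = 360 * 128
        rec = make_rec(np.zeros((8, n)), trials=[(0, n, 1)])
        wins = segment_windows(rec, PreprocConfig(window_s=1.0))
        assert len(wins) == 360
        assert all(w.label == 1 and w.data.shape == (8, 128) for w in wins)

    @pytest.mark.parametrize("window_s", [0.1, 0.2, 0.5, 1, 2, 5, 10])
    def test_window_counts_match_closed_form(self, window_s):
        n = 60 * 128
        rec = make_rec(np.zeros((8, n)), trials=[(0, n, 0)])
        wins = segment_windows(rec, PreprocConfig(window_s=window_s))
        w = int(round(window_s * 128))
        assert len(wins) == (n - w) // w + 1

    def test_fractional_window_rounds_to_13_samples(self):
        rec = make_rec(np.zeros((8, 128)))
        wins = segment_windows(rec, PreprocConfig(window_s=0.1))
        assert wins[0].data.shape[1] == 13  # round(0.1 * 128) = round(12.8)

    def test_overlapping_stride(self):
        rec = make_rec(np.zeros((8, 128)))
        wins = segment_windows(rec, with_window(PreprocConfig(), 0.5, stride_s=0.25))
        assert len(wins) == (128 - 64) // 32 + 1

    def test_window_longer_than_trial_yields_none_and_warns(self, caplog):
        rec = make_rec(np.zeros((8, 64)))
        with caplog.at_level("WARNING"):
            wins = segment_windows(rec, PreprocConfig(window_s=1.0))
        assert wins == []
        assert "shorter than window" in caplog.text


def test_full_chain_is_stable_under_reapplication(rng):
    spec_data = rng.normal(size=(8, 512 * 4)) + 5.0
    rec = make_rec(spec_data, fs=512.0, trials=[(0, 2048, 0)])
    cfg = PreprocConfig()
    once = preprocess_chain(rec, cfg)
    twice = preprocess_chain(once, cfg)
    # idempotent up to filter-edge effects
    mid = slice(64, -64)
    r = np.corrcoef(once.data[0, mid], twice.data[0, mid])[0, 1]
    assert r > 0.99


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocConfig(filter_order=5)
    with pytest.raises(ValueError):
        PreprocConfig(band_low=0.0)
    with pytest.raises(ValueError):
        PreprocConfig(band_high=70.0)
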