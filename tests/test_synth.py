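"""Synthetic EEG generator: montage geometry, rhythms, noise and labels."""

import numpy as np
import pytest
from scipy import signal

from spikewav import EEGRecording, SynthSpec, generate_dataset, generate_recording, make_montage


def band_power(data, fs, lo, hi):
    f, p = signal.welch(data, fs=fs, nperseg=min(256, data.shape[-1]))
    sel = (f >= lo) & (f <= hi)
    return p[..., sel].sum(axis=-1)


class TestMontage:
    def test_8_channel_symmetric_pairs(self):
        m = make_montage(8)
        assert set(m.channel_names) == {"F3", "F4", "T7", "T8", "P3", "P4", "O1", "O2"}

    def test_32_channel_names_unique_and_on_disc(self):
        m = make_montage(32)
        assert len(set(m.channel_names)) == 32
        assert np.all(np.linalg.norm(m.positions, axis=1) <= 1.0)

    def test_64_channel_mirror_map_exhaustive(self):
        m = make_montage(64)
        pos = {n: p for n, p in zip(m.channel_names, m.positions)}
        left = [n for n, p in pos.items() if p[0] < 0]
        assert left  # sanity
        for name in left:
            head = name.rstrip("0123456789")
            num = int(name[len(head):])
            mirror = f"{head}{num + 1}"
            assert mirror in pos, f"no mirror for {name}"
            assert pos[mirror][0] == pytest.approx(-pos[name][0])
            assert pos[mirror][1] == pytest.approx(pos[name][1])

    def test_unsupported_count_rejected(self):
        with pytest.raises(ValueError):
            make_montage(13)


class TestGeneration:
    def test_determinism_bit_identical(self, small_spec):
        a = generate_recording(small_spec, 0)
        b = generate_recording(small_spec, 0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_symmetric_alpha_when_asymmetry_is_one(self):
        spec = SynthSpec(n_channels=32, trial_length_s=8.0, n_trials_per_class=3,
                         alpha_asymmetry=(1.0, 1.0), noise_scale=0.0, seed=5)
        rec = generate_recording(spec, 0)
        left, right, _ = rec.montage.hemisphere_indices()
        a = band_power(rec.data, rec.fs, 8, 13)
        assert abs(a[left].mean() / a[right].mean() - 1) < 0.10

    def test_pink_noise_spectral_slope(self):
        spec = SynthSpec(n_channels=8, trial_length_s=60.0, n_trials_per_class=1,
                         band_powers={}, noise_exponent=1.0, seed=3)
        rec = generate_recording(spec, 0)
        f, p = signal.welch(rec.data, fs=rec.fs, nperseg=1024)
        sel = (f >= 2) & (f <= 40)
        slopes = [
            np.polyfit(np.log(f[sel]), np.log(p[ch, sel]), 1)[0]
            for ch in range(rec.data.shape[0])
        ]
        assert abs(np.mean(slopes) - (-1.0)) < 0.2

    def test_pure_band_concentrates_variance(self):
        spec = SynthSpec(n_channels=8, trial_length_s=10.0, n_trials_per_class=1,
                         band_powers={"alpha": 1.0}, noise_scale=0.0, seed=2)
        rec = generate_recording(spec, 0)
        total = band_power(rec.data, rec.fs, 0.5, 63.0)
        inband = band_power(rec.data, rec.fs, 8.0, 13.0)
        assert np.all(inband / total >= 0.90)

    def test_bursts_stable_under_noise_level_change(self):
        base = SynthSpec(n_channels=8, trial_length_s=2.0, n_trials_per_class=1, seed=11)
        quiet = SynthSpec(n_channels=8, trial_length_s=2.0, n_trials_per_class=1,
                          noise_scale=0.0, seed=11)
        loud = SynthSpec(n_channels=8, trial_length_s=2.0, n_trials_per_class=1,
                         noise_scale=2.0, seed=11)
        b = generate_recording(base, 0).data
        q = generate_recording(quiet, 0).data
        l = generate_recording(loud, 0).data
        # noise is additive on a seed-stable burst component
        np.testing.assert_allclose(l - q, 2.0 * (b - q), atol=1e-9)


class TestDataset:
    def test_balanced_labels_and_counts(self):
        spec = SynthSpec(n_channels=8, trial_length_s=1.0, n_trials_per_class=10, seed=0)
        rec = generate_dataset(spec)
        labels = rec.labels
        assert len(labels) == 20
        assert (labels == 0).sum() == 10 and (labels == 1).sum() == 10

    def test_seed_changes_order_not_counts(self):
        kw = dict(n_channels=8, trial_length_s=1.0, n_trials_per_class=10)
        a = generate_dataset(SynthSpec(seed=1, **kw)).labels
        b = generate_dataset(SynthSpec(seed=2, **kw)).labels
        assert (a != b).any()
        assert (a == 0).sum() == (b == 0).sum() == 10

    def test_trial_level_alpha_ratio_separates_classes(self):
        spec = SynthSpec(n_channels=32, trial_length_s=4.0, n_trials_per_class=8, seed=9)
        rec = generate_dataset(spec)
        left, right, _ = rec.montage.hemisphere_indices()
        ratios = {0: [], 1: []}
        for start, end, lab in rec.trials:
            a = band_power(rec.data[:, start:end], rec.fs, 8, 13)
            ratios[lab].append(a[left].mean() / a[right].mean())
        assert min(ratios[0]) > max(ratios[1])  # non-overlapping distributions


class TestValidation:
    def test_spec_rejects_undersampled_bands(self):
        with pytest.raises(ValueError):
            SynthSpec(fs=40.0, band_powers={"gamma": 1.0})

    def test_spec_rejects_bad_asymmetry(self):
        with pytest.raises(ValueError):
            SynthSpec(alpha_asymmetry=(1.0, -0.5))

    def test_recording_rejects_overlapping_trials(self, montage8):
        data = np.zeros((8, 100))
        with pytest.raises(ValueError):
            EEGRecording(data, 128.0, montage8, [(0, 60, 0), (50, 100, 1)])
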