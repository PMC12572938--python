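"""Synthetic multi-channel EEG with a known, class-dependent spatial structure.

The generator emulates the statistical shape of scalp EEG used in
emotion-recognition and auditory-attention benchmarks: band-limited
oscillatory bursts in the canonical rhythms (delta 0.5-4 Hz, theta 4-8 Hz,
alpha 8-13 Hz, beta 13-30 Hz, gamma > 30 Hz) riding on pink (1/f^beta)
background noise, organised into labelled trials.  Class structure is a
hemispheric alpha-power asymmetry: a per-class left:right amplitude ratio
applied to the alpha bursts, the kind of lateralisation that left/right
auditory attention produces in real recordings.

Everything is deterministic given ``SynthSpec.seed``: bursts and noise use
independent seed streams, so changing the noise level never changes the
oscillatory content of a trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BANDS",
    "Montage",
    "SynthSpec",
    "EEGRecording",
    "make_montage",
    "generate_recording",
    "generate_dataset",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

# Head-plane rows (nasion at top, y > 0 frontal) for 10-20-style labels.
_ROW_Y = {
    "Fp": 0.80, "AF": 0.62, "F": 0.45, "FT": 0.22, "FC": 0.22,
    "T": 0.0, "C": 0.0, "TP": -0.22, "CP": -0.22,
    "P": -0.45, "PO": -0.62, "O": -0.80, "I": -0.92,
}

_NAMES_8 = ["F3", "F4", "T7", "T8", "P3", "P4", "O1", "O2"]

_NAMES_32 = [
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1", "P3",
    "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "Fz", "F4", "F8", "FC6",
    "FC2", "Cz", "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
]

_NAMES_64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]


def _parse_label(name: str) -> tuple[str, int]:
    """Split e.g. 'FC5' -> ('FC', 5), 'Oz' -> ('O', 0), 'P10' -> ('P', 10)."""
    i = 0
    while i < len(name) and not (name[i].isdigit() or name[i] == "z"):
        i += 1
    prefix, rest = name[:i], name[i:]
    if rest == "z" or rest == "":
        return prefix, 0
    return prefix, int(rest)


def _position(name: str) -> tuple[float, float]:
    prefix, num = _parse_label(name)
    y = _ROW_Y[prefix]
    if num == 0:
        return 0.0, y
    ring = (num + 1) // 2  # 1,2 innermost ... 9,10 outermost
    x = (ring / 5.0) * np.sqrt(max(0.0, 1.0 - y * y))
    if num % 2 == 1:  # odd = left hemisphere
        x = -x
    return float(x), float(y)


@dataclass(frozen=True)
class Montage:
    """Electrode names and 2D head-plane positions (unit disc, nasion up)."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self):
        if len(self.channel_names) < 4:
            raise ValueError("montage needs at least 4 channels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.channel_names), 2):
            raise ValueError("positions must be (n_channels, 2)")
        r = np.linalg.norm(self.positions, axis=1)
        if np.any(r > 1.0 + 1e-12):
            raise ValueError("all positions must lie within the unit disc")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def hemisphere_indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(left, right, midline) channel indices from the x-coordinate sign."""
        x = self.positions[:, 0]
        return np.where(x < 0)[0], np.where(x > 0)[0], np.where(x == 0)[0]


def make_montage(n_channels: int) -> Montage:
    """A 10-20-style montage of 8, 32 (DEAP-like) or 64 (BioSemi-like) channels."""
    try:
        names = {8: _NAMES_8, 32: _NAMES_32, 64: _NAMES_64}[n_channels]
    except KeyError:
        raise ValueError(f"unsupported channel count {n_channels}; choose 8, 32 or 64") from None
    pos = np.array([_position(n) for n in names])
    return Montage(tuple(names), pos)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the stated synthetic world.

    ``band_powers`` maps rhythm name to burst amplitude (arbitrary
    microvolt-scale units); ``alpha_asymmetry`` is the per-class
    left:right alpha amplitude ratio (class index -> ratio);
    ``noise_exponent`` is the pink-noise 1/f^beta exponent and
    ``noise_scale`` its standard deviation in the same units as the
    bursts.
    """

    n_channels: int = 32
    fs: float = 128.0
    trial_length_s: float = 5.0
    n_trials_per_class: int = 50
    band_powers: dict = field(
        default_factory=lambda: {"delta": 1.0, "theta": 0.8, "alpha": 1.2, "beta": 0.5}
    )
    alpha_asymmetry: tuple[float, ...] = (1.5, 0.67)
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    oscillators_per_band: int = 3
    am_depth: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.trial_length_s <= 0:
            raise ValueError("trial_length_s must be positive")
        if any(a <= 0 for a in self.alpha_asymmetry):
            raise ValueError("alpha_asymmetry ratios must be positive")
        used = [BANDS[b][1] for b, a in self.band_powers.items() if a > 0]
        if used and self.fs <= 2 * max(used):
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge used ({max(used)} Hz)"
            )

    @property
    def n_classes(self) -> int:
        return len(self.alpha_asymmetry)

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_length_s * self.fs))


@dataclass
class EEGRecording:
    """Multi-channel signal with montage and labelled trial spans."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    montage: Montage
    trials: list[tuple[int, int, int]]  # (start_sample, end_sample, label)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        n = self.data.shape[1]
        prev_end = 0
        for start, end, _ in sorted(self.trials):
            if not (0 <= start < end <= n):
                raise ValueError(f"trial span ({start}, {end}) outside data of length {n}")
            if start < prev_end:
                raise ValueError("trial spans must not overlap")
            prev_end = end

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.trials])


def _pink_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^beta noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _alpha_gains(asym: float) -> tuple[float, float, float]:
    """(left, right, midline) amplitude gains realising a left:right ratio."""
    g_left = float(np.sqrt(asym))
    g_right = 1.0 / g_left
    return g_left, g_right, 0.5 * (g_left + g_right)


def _trial_bursts(
    spec: SynthSpec, montage: Montage, class_label: int, trial_index: int
) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0, class_label, trial_index)))
    n = spec.trial_samples
    t = np.arange(n) / spec.fs
    g_left, g_right, g_mid = _alpha_gains(spec.alpha_asymmetry[class_label])
    x_coord = montage.positions[:, 0]
    k = spec.oscillators_per_band
    out = np.zeros((montage.n_channels, n))
    for ch in range(montage.n_channels):
        for band, amp in spec.band_powers.items():
            if amp <= 0:
                continue
            lo, hi = BANDS[band]
            gain = amp
            if band == "alpha":
                gain *= g_left if x_coord[ch] < 0 else g_right if x_coord[ch] > 0 else g_mid
            # A rhythm is a superposition of k independently amplitude-
            # modulated oscillators; 1/sqrt(k) keeps band variance at
            # amp^2/2 regardless of k.
            for _ in range(k):
                f = rng.uniform(lo, hi)
                phase = rng.uniform(0, 2 * np.pi)
                am_f = rng.uniform(0.2, 0.8)
                am_phase = rng.uniform(0, 2 * np.pi)
                envelope = 1.0 + spec.am_depth * np.sin(2 * np.pi * am_f * t + am_phase)
                out[ch] += (gain / np.sqrt(k)) * envelope * np.sin(2 * np.pi * f * t + phase)
    return out


def _trial_noise(spec: SynthSpec, class_label: int, trial_index: int, n_ch: int) -> np.ndarray:
    if spec.noise_scale == 0:
        return np.zeros((n_ch, spec.trial_samples))
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1, class_label, trial_index)))
    return spec.noise_scale * np.stack(
        [_pink_noise(spec.trial_samples, spec.noise_exponent, rng) for _ in range(n_ch)]
    )


def _make_trial(spec: SynthSpec, montage: Montage, class_label: int, trial_index: int):
    return _trial_bursts(spec, montage, class_label, trial_index) + _trial_noise(
        spec, class_label, trial_index, montage.n_channels
    )


def generate_recording(spec: SynthSpec, class_label: int) -> EEGRecording:
    """All trials of one class, concatenated in time.  Deterministic in seed."""
    montage = make_montage(spec.n_channels)
    n = spec.trial_samples
    chunks, trials = [], []
    for i in range(spec.n_trials_per_class):
        chunks.append(_make_trial(spec, montage, class_label, i))
        trials.append((i * n, (i + 1) * n, class_label))
    return EEGRecording(np.concatenate(chunks, axis=1), spec.fs, montage, trials)


def generate_dataset(spec: SynthSpec) -> EEGRecording:
    """Balanced two-class (or k-class) recording, trial order shuffled by seed."""
    if spec.n_trials_per_class < 1:
        raise ValueError("n_trials_per_class must be >= 1")
    montage = make_montage(spec.n_channels)
    order = [(c, i) for c in range(spec.n_classes) for i in range(spec.n_trials_per_class)]
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)))
    rng.shuffle(order)
    n = spec.trial_samples
    chunks, trials = [], []
    for k, (c, i) in enumerate(order):
        chunks.append(_make_trial(spec, montage, c, i))
        trials.append((k * n, (k + 1) * n, c))
    return EEGRecording(np.concatenate(chunks, axis=1), spec.fs, montage, trials)
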