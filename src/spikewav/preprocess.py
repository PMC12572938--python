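"""Standard EEG preprocessing chain: common-average reference, Chebyshev-II
band-pass, polyphase resampling to 128 Hz, per-trial standardisation, rhythm
band extraction, and sliding decision windows.

The chain order is fixed (re-reference -> band-pass -> resample ->
normalise).  Filtering is zero-phase (forward-backward second-order
sections), so the quoted stopband attenuation is effectively doubled and
no phase distortion is introduced — appropriate for offline decoding.
A "6th-order" band-pass means a 6th-order transfer function: the
low-pass prototype order passed to the designer is ``filter_order // 2``
because the band-pass transform doubles it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .synth import EEGRecording

__all__ = [
    "PreprocConfig",
    "EEGWindow",
    "rereference_average",
    "bandpass_chebyshev2",
    "resample_to",
    "normalize_trial",
    "extract_band",
    "segment_windows",
    "preprocess_chain",
]

log = logging.getLogger(__name__)

ALPHA_BAND = (8.0, 13.0)


@dataclass(frozen=True)
class PreprocConfig:
    band_low: float = 1.0
    band_high: float = 32.0
    filter_order: int = 6
    target_fs: float = 128.0
    stopband_atten_db: float = 40.0
    window_s: float = 1.0
    stride_s: float | None = None  # None = window length (non-overlapping)

    def __post_init__(self):
        if not (0 < self.band_low < self.band_high < self.target_fs / 2):
            raise ValueError("need 0 < band_low < band_high < target_fs/2")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError("filter_order must be even and >= 2")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")

    @property
    def stride(self) -> float:
        return self.stride_s if self.stride_s is not None else self.window_s


@dataclass
class EEGWindow:
    """One decision window: the unit on which a single prediction is made."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    label: int
    source_trial: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("window data must be finite")


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Common-average reference: subtract the instantaneous cross-channel mean."""
    if rec.data.shape[0] < 2:
        raise ValueError("average re-referencing needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(data, rec.fs, rec.montage, list(rec.trials))


def _cheby2_sos(low: float, high: float, order: int, atten_db: float, fs: float):
    # For Chebyshev-II the critical frequencies are the stopband edges, i.e.
    # attenuation reaches atten_db at `low` and `high`.
    return signal.cheby2(order // 2, atten_db, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_chebyshev2(rec: EEGRecording, cfg: PreprocConfig) -> EEGRecording:
    if rec.fs <= 2 * cfg.band_high:
        raise ValueError(f"band_high={cfg.band_high} at or above Nyquist for fs={rec.fs}")
    sos = _cheby2_sos(cfg.band_low, cfg.band_high, cfg.filter_order, cfg.stopband_atten_db, rec.fs)
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(data, rec.fs, rec.montage, list(rec.trials))


def resample_to(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-aliased polyphase downsampling; trial spans rescaled with it."""
    if target_fs > rec.fs:
        raise ValueError(f"upsampling {rec.fs} -> {target_fs} Hz is out of scope")
    if target_fs == rec.fs:
        return EEGRecording(rec.data.copy(), rec.fs, rec.montage, list(rec.trials))
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    r = float(frac)
    trials = [
        (int(np.floor(s * r)), int(np.ceil(e * r)), lab) for s, e, lab in rec.trials
    ]
    return EEGRecording(data, target_fs, rec.montage, trials)


def normalize_trial(rec: EEGRecording) -> EEGRecording:
    """Per channel, per trial: zero mean and unit variance."""
    data = rec.data.copy()
    for ti, (start, end, _) in enumerate(rec.trials):
        seg = data[:, start:end]
        sd = seg.std(axis=1, keepdims=True)
        flat = np.where(sd.ravel() == 0)[0]
        if flat.size:
            names = [rec.montage.channel_names[i] for i in flat]
            raise ValueError(f"constant channel(s) {names} in trial {ti}")
        data[:, start:end] = (seg - seg.mean(axis=1, keepdims=True)) / sd
    return EEGRecording(data, rec.fs, rec.montage, list(rec.trials))


def extract_band(rec: EEGRecording, low: float = ALPHA_BAND[0], high: float = ALPHA_BAND[1],
                 order: int = 6) -> EEGRecording:
    """Band-pass restricted copy (defaults to the alpha rhythm, 8-13 Hz).

    Unlike the Chebyshev-II chain filter (whose critical frequencies are
    stopband edges), rhythm extraction must keep the whole requested band:
    a Butterworth design with ``low``/``high`` as passband edges leaves
    oscillations anywhere inside the band untouched.
    """
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(f"invalid band ({low}, {high}) for fs={rec.fs}")
    sos = signal.butter(order // 2, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(data, rec.fs, rec.montage, list(rec.trials))


def segment_windows(rec: EEGRecording, cfg: PreprocConfig) -> list[EEGWindow]:
    """Sliding decision windows per trial; fractional lengths round to nearest."""
    win = int(round(cfg.window_s * rec.fs))
    stride = max(1, int(round(cfg.stride * rec.fs)))
    if win < 1:
        raise ValueError("window shorter than one sample")
    out: list[EEGWindow] = []
    for ti, (start, end, lab) in enumerate(rec.trials):
        n = end - start
        if n < win:
            log.warning("trial %d (%d samples) shorter than window (%d samples); skipped", ti, n, win)
            continue
        count = (n - win) // stride + 1
        for k in range(count):
            s = start + k * stride
            out.append(EEGWindow(rec.data[:, s : s + win].copy(), rec.fs, lab, ti))
    return out


def preprocess_chain(rec: EEGRecording, cfg: PreprocConfig) -> EEGRecording:
    """The full fixed-order chain (no band extraction or windowing)."""
    rec = rereference_average(rec)
    rec = bandpass_chebyshev2(rec, cfg)
    rec = resample_to(rec, cfg.target_fs)
    return normalize_trial(rec)


def with_window(cfg: PreprocConfig, window_s: float, stride_s: float | None = None) -> PreprocConfig:
    return _dc_replace(cfg, window_s=window_s, stride_s=stride_s)
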