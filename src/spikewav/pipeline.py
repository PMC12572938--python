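"""End-to-end glue: recording -> preprocessing -> alpha topomaps -> tensors.

This is the path the CLI and the synthetic-learning experiment share:
the fixed preprocessing chain, alpha-band extraction, sliding decision
windows, per-window topographic encoding, and stacking into model-ready
arrays.
"""

from __future__ import annotations

import numpy as np

from .model import stack_windows
from .preprocess import PreprocConfig, extract_band, preprocess_chain, segment_windows
from .synth import EEGRecording, SynthSpec, generate_dataset
from .topomap import EncodedWindow, encode_window

__all__ = ["encode_recording", "make_synthetic_encoded"]


def encode_recording(
    rec: EEGRecording,
    pcfg: PreprocConfig | None = None,
    t_steps: int = 4,
    grid: int = 32,
    band: tuple[float, float] = (8.0, 13.0),
) -> list[EncodedWindow]:
    """Full front end: preprocess, band-limit, window, encode."""
    pcfg = pcfg or PreprocConfig()
    rec = preprocess_chain(rec, pcfg)
    rec = extract_band(rec, *band)
    windows = segment_windows(rec, pcfg)
    return [encode_window(w, rec.montage, t_steps, grid, grid) for w in windows]


def make_synthetic_encoded(
    spec: SynthSpec | None = None,
    pcfg: PreprocConfig | None = None,
    t_steps: int = 4,
    grid: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate the synthetic lateralised-alpha dataset and encode it."""
    spec = spec or SynthSpec()
    rec = generate_dataset(spec)
    return stack_windows(encode_recording(rec, pcfg, t_steps, grid))
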