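"""Topographic encoding: per-channel alpha power -> 2D head map -> SNN input.

Each decision window is reduced to one scalar per electrode (mean squared
amplitude of the already band-limited signal), interpolated onto an H x W
head-plane grid, and replicated over the simulation time steps as a
constant ("direct") encoding — the first spiking layer converts it into
spike trains implicitly.

Interpolation is inverse-distance weighting (power 2) over the k nearest
electrodes.  IDW is linear in the channel values and produces convex
combinations only, so the map never overshoots the electrode values —
properties a spline interpolant would not give.  Pixels outside the unit
disc (off the scalp) are zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EEGWindow
from .synth import Montage

__all__ = ["EncodedWindow", "channel_power", "project_topomap", "encode_timesteps", "encode_window"]

IDW_POWER = 2.0
IDW_NEIGHBOURS = 4


@dataclass
class EncodedWindow:
    """One decision window as a (T, C, H, W) spike-ready array."""

    x: np.ndarray
    label: int

    def __post_init__(self):
        t, _, h, w = self.x.shape
        if t < 1:
            raise ValueError("need at least one time step")
        if (h & (h - 1)) or (w & (w - 1)):
            raise ValueError(f"grid dims must be powers of two for Haar halving, got {h}x{w}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("encoded window must be finite")


def channel_power(win: EEGWindow) -> np.ndarray:
    """Mean squared amplitude per channel (band power for band-limited input)."""
    if win.data.shape[1] == 0:
        raise ValueError("empty window")
    return np.mean(np.square(win.data), axis=1)


def _idw_weights(montage: Montage, h: int, w: int, k: int = IDW_NEIGHBOURS) -> np.ndarray:
    """(H*W, n_channels) sparse-ish weight matrix; rows of off-scalp pixels are 0."""
    ys = np.linspace(1.0, -1.0, h)  # row 0 = front (nasion)
    xs = np.linspace(-1.0, 1.0, w)  # column 0 = left hemisphere
    gx, gy = np.meshgrid(xs, ys)
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)
    inside = np.linalg.norm(grid, axis=1) <= 1.0
    d2 = np.sum((grid[:, None, :] - montage.positions[None, :, :]) ** 2, axis=2)
    k = min(k, montage.n_channels)
    weights = np.zeros((h * w, montage.n_channels))
    nearest = np.argpartition(d2, k - 1, axis=1)[:, :k]
    rows = np.arange(h * w)[:, None]
    dk = d2[rows, nearest]
    eps = 1e-12
    wk = 1.0 / (dk ** (IDW_POWER / 2.0) + eps)
    # Exact hits: collapse the weight onto the coincident electrode.
    hit = dk < 1e-12
    wk = np.where(hit.any(axis=1, keepdims=True), hit.astype(float), wk / wk.sum(axis=1, keepdims=True))
    weights[rows, nearest] = wk
    weights[~inside] = 0.0
    return weights


_weight_cache: dict[tuple, np.ndarray] = {}


def _cached_weights(montage: Montage, h: int, w: int) -> np.ndarray:
    key = (montage.channel_names, h, w)
    if key not in _weight_cache:
        _weight_cache[key] = _idw_weights(montage, h, w)
    return _weight_cache[key]


def project_topomap(values: np.ndarray, montage: Montage, h: int = 32, w: int = 32) -> np.ndarray:
    """Interpolate per-channel scalars onto an H x W head-plane grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != (montage.n_channels,):
        raise ValueError(
            f"got {values.shape[0] if values.ndim == 1 else values.shape} values "
            f"for a {montage.n_channels}-channel montage"
        )
    if h < 8 or w < 8:
        raise ValueError("grid must be at least 8x8")
    return (_cached_weights(montage, h, w) @ values).reshape(h, w)


def encode_timesteps(topo: np.ndarray, t_steps: int, label: int, c: int = 1) -> EncodedWindow:
    """Replicate a map across T simulation steps (direct/constant encoding)."""
    if t_steps < 1:
        raise ValueError("need at least one time step")
    h, w = topo.shape
    x = np.broadcast_to(topo, (t_steps, c, h, w)).copy()
    return EncodedWindow(x.astype(np.float32), label)


def encode_window(
    win: EEGWindow, montage: Montage, t_steps: int = 4, h: int = 32, w: int = 32
) -> EncodedWindow:
    """channel_power -> project_topomap -> encode_timesteps, in one call."""
    topo = project_topomap(channel_power(win), montage, h, w)
    return encode_timesteps(topo, t_steps, win.label)
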