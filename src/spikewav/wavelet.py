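"""Single-level orthonormal 2D Haar wavelet transform and the sub-band branch.

The analysis transform splits a feature map into four half-resolution
sub-bands on each non-overlapping 2x2 block ``[[a, b], [c, d]]``:

    LL = (a + b + c + d) / 2      approximation (low frequencies)
    LH = (a - b + c - d) / 2      horizontal detail
    HL = (a + b - c - d) / 2      vertical detail
    HH = (a - b - c + d) / 2      diagonal detail

With the 1/2 gain the transform is orthonormal: it preserves the L2 norm
exactly (so the decomposition is an isometry and the synthesis transform
is both inverse and adjoint), which is what makes the wavelet stage of
the encoder a Lipschitz-1 map.

The learned branch (:class:`WaveletBranch`) decomposes a spike-feature
map, concatenates the LL/LH/HL sub-bands channel-wise (the diagonal band
is excluded by default — it carries the noisiest spatial frequencies —
but ``include_hh=True`` keeps it), applies a local 3x3 convolution +
batch norm + LIF spiking layer producing four spike-valued sub-bands, and
reconstructs a full-resolution map by the inverse transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import BatchNorm, Conv2d, LIF, Module
from .spiking import LIFConfig

__all__ = ["SubBands", "haar_dwt2", "haar_idwt2", "WaveletBranch"]


@dataclass
class SubBands:
    """The four half-resolution Haar sub-bands of a (..., H, W) map."""

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray

    def __post_init__(self):
        shapes = {self.ll.shape, self.lh.shape, self.hl.shape, self.hh.shape}
        if len(shapes) != 1:
            raise ValueError(f"sub-band shapes differ: {shapes}")

    def stack(self) -> np.ndarray:
        """Bands along a new leading axis, order (LL, LH, HL, HH)."""
        return np.stack([self.ll, self.lh, self.hl, self.hh])

    def energy(self) -> float:
        return float(sum(np.sum(np.square(b)) for b in (self.ll, self.lh, self.hl, self.hh)))


def _quads(x: np.ndarray):
    return x[..., 0::2, 0::2], x[..., 0::2, 1::2], x[..., 1::2, 0::2], x[..., 1::2, 1::2]


def haar_dwt2(x: np.ndarray) -> SubBands:
    """Single-level orthonormal 2D Haar analysis of a (..., H, W) array."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] % 2 or x.shape[-2] % 2:
        raise ValueError(f"spatial dims must be even, got {x.shape[-2:]}")
    a, b, c, d = _quads(x)
    return SubBands(
        ll=(a + b + c + d) * 0.5,
        lh=(a - b + c - d) * 0.5,
        hl=(a + b - c - d) * 0.5,
        hh=(a - b - c + d) * 0.5,
    )


def haar_idwt2(sb: SubBands) -> np.ndarray:
    """Inverse (= adjoint) of :func:`haar_dwt2`; exact reconstruction."""
    ll, lh, hl, hh = (np.asarray(v, dtype=float) for v in (sb.ll, sb.lh, sb.hl, sb.hh))
    h, w = ll.shape[-2:]
    out = np.empty(ll.shape[:-2] + (2 * h, 2 * w), dtype=ll.dtype)
    out[..., 0::2, 0::2] = (ll + lh + hl + hh) * 0.5
    out[..., 0::2, 1::2] = (ll - lh + hl - hh) * 0.5
    out[..., 1::2, 0::2] = (ll + lh - hl - hh) * 0.5
    out[..., 1::2, 1::2] = (ll - lh - hl + hh) * 0.5
    return out


# -- autodiff versions operating on channel-stacked Tensors -------------------


def dwt2_t(x: Tensor) -> Tensor:
    """(..., C, H, W) Tensor -> (..., 4C, H/2, W/2); quarters are LL,LH,HL,HH."""
    a = x.strided2(0, 0)
    b = x.strided2(0, 1)
    c = x.strided2(1, 0)
    d = x.strided2(1, 1)
    ll = (a + b + c + d) * 0.5
    lh = (a - b + c - d) * 0.5
    hl = (a + b - c - d) * 0.5
    hh = (a - b - c + d) * 0.5
    return concat([ll, lh, hl, hh], axis=-3)


def _interleave_cols(p: Tensor, q: Tensor) -> Tensor:
    sh = p.shape
    p = p.reshape(*sh, 1)
    q = q.reshape(*sh, 1)
    return concat([p, q], axis=-1).reshape(*sh[:-1], 2 * sh[-1])


def _interleave_rows(p: Tensor, q: Tensor) -> Tensor:
    sh = p.shape
    p = p.reshape(*sh[:-1], 1, sh[-1])
    q = q.reshape(*sh[:-1], 1, sh[-1])
    return concat([p, q], axis=-2).reshape(*sh[:-2], 2 * sh[-2], sh[-1])


def idwt2_t(bands: Tensor, c: int) -> Tensor:
    """Inverse of :func:`dwt2_t` for a (..., 4C, h, w) Tensor."""
    ax = bands.ndim - 3
    ll = bands.narrow(ax, 0, c)
    lh = bands.narrow(ax, c, c)
    hl = bands.narrow(ax, 2 * c, c)
    hh = bands.narrow(ax, 3 * c, c)
    a = (ll + lh + hl + hh) * 0.5
    b = (ll - lh + hl - hh) * 0.5
    cc = (ll + lh - hl - hh) * 0.5
    d = (ll - lh - hl + hh) * 0.5
    top = _interleave_cols(a, b)
    bot = _interleave_cols(cc, d)
    return _interleave_rows(top, bot)


class WaveletBranch(Module):
    """Haar-decompose, filter sub-bands with a spiking conv stage, reconstruct.

    Operates on (T, B, C, H, W) Tensors; H and W must be even.  The 3x3
    convolution maps the concatenated input bands (3C channels, or 4C with
    ``include_hh=True``) to 4C output channels whose quarters are read as
    (LL, LH, HL, HH) spike sub-bands for the inverse transform.  Weights
    start as an identity pass-through of the LL quarter (zeros elsewhere)
    so an untrained branch does not inject noise.
    """

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        include_hh: bool = False,
        lif_cfg: LIFConfig | None = None,
    ):
        self.channels = channels
        self.include_hh = include_hh
        in_ch = 4 * channels if include_hh else 3 * channels
        self.conv = Conv2d(in_ch, 4 * channels, rng, kernel=3, stride=1, padding=1, init="zeros")
        w = self.conv.w.data
        for i in range(channels):  # LL quarter passes through at init
            w[i, i, 1, 1] = 1.0
        self.bn = BatchNorm(4 * channels, channel_axis=1)
        self.lif = LIF(lif_cfg)
        self.last_coeffs: Tensor | None = None  # analysis coefficients, for L1 penalty

    def filter_bands(self, bands: Tensor) -> Tensor:
        """Eq-style sub-band filtering: (T, B, 4C, h, w) -> spike sub-bands."""
        c = self.channels
        t_steps, bsz = bands.shape[0], bands.shape[1]
        h, w = bands.shape[-2:]
        flat = bands.reshape(t_steps * bsz, 4 * c, h, w)
        inp = flat if self.include_hh else flat.narrow(1, 0, 3 * c)
        z = self.bn(self.conv(inp))
        z = z.reshape(t_steps, bsz, 4 * c, h, w)
        return self.lif(z)

    def __call__(self, x: Tensor) -> Tensor:
        t_steps, bsz, c, h, w = x.shape
        flat = x.reshape(t_steps * bsz, c, h, w)
        bands = dwt2_t(flat).reshape(t_steps, bsz, 4 * c, h // 2, w // 2)
        self.last_coeffs = bands
        spikes = self.filter_bands(bands)
        flat_s = spikes.reshape(t_steps * bsz, 4 * c, h // 2, w // 2)
        recon = idwt2_t(flat_s, c)
        return recon.reshape(t_steps, bsz, c, h, w)
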