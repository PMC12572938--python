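"""Spiking self-attention and its fusion with the wavelet branch.

The attention path never uses a softmax: Q, K and V are binary spike
tensors (Linear + BatchNorm + LIF per projection), the score
``Q K^T V`` is therefore a non-negative integer tensor, and a scaling
factor ``s`` (default 0.125, the spikformer convention) keeps its
magnitude in range before the output LIF re-binarises it.

The block fuses this attention output with the Haar wavelet-branch
reconstruction of the same tokens (laid out on their sqrt(N) x sqrt(N)
spatial grid) by channel-wise concatenation, followed by Linear(2d -> d)
+ BatchNorm + LIF so the residual stream keeps dimension d and the block
output stays binary.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import BatchNorm, LIF, Linear, Module
from .spiking import LIFConfig, lif_sequence
from .wavelet import WaveletBranch

__all__ = ["attention_scores", "spiking_attention", "SpikingSelfAttention", "SWSABlock"]


def attention_scores(q: np.ndarray, k: np.ndarray, v: np.ndarray, scale_s: float = 0.125):
    """Pre-neuron attention current ``(Q K^T) V * s`` for (T, N, d) spike arrays."""
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    return np.matmul(np.matmul(q, np.swapaxes(k, -1, -2)), v) * scale_s


def spiking_attention(
    q: np.ndarray, k: np.ndarray, v: np.ndarray, scale_s: float = 0.125,
    cfg: LIFConfig | None = None,
) -> np.ndarray:
    """Functional single-head spiking attention on (T, N, d) binary arrays."""
    cur = attention_scores(q, k, v, scale_s)
    return lif_sequence(cur, cfg or LIFConfig())


class SpikingSelfAttention(Module):
    """Multi-head spiking attention: Q/K/V spikes, integer scores, output LIF."""

    def __init__(
        self,
        d: int,
        heads: int,
        rng: np.random.Generator,
        scale_s: float = 0.125,
        lif_cfg: LIFConfig | None = None,
    ):
        if d % heads:
            raise ValueError(f"embedding dim {d} not divisible by {heads} heads")
        self.d, self.heads, self.scale_s = d, heads, scale_s
        self.w_q, self.w_k, self.w_v = (Linear(d, d, rng) for _ in range(3))
        self.bn_q, self.bn_k, self.bn_v = (BatchNorm(d) for _ in range(3))
        self.lif_q, self.lif_k, self.lif_v = (LIF(lif_cfg) for _ in range(3))
        self.lif_attn = LIF(lif_cfg)
        self.w_o = Linear(d, d, rng)
        self.bn_o = BatchNorm(d)
        self.lif_o = LIF(lif_cfg)

    def form_qkv(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        q = self.lif_q(self.bn_q(self.w_q(x)))
        k = self.lif_k(self.bn_k(self.w_k(x)))
        v = self.lif_v(self.bn_v(self.w_v(x)))
        return q, k, v

    def _split_heads(self, x: Tensor) -> Tensor:
        t, b, n, d = x.shape
        dk = d // self.heads
        return x.reshape(t, b, n, self.heads, dk).transpose(0, 1, 3, 2, 4)

    def _merge_heads(self, x: Tensor) -> Tensor:
        t, b, h, n, dk = x.shape
        return x.transpose(0, 1, 3, 2, 4).reshape(t, b, n, h * dk)

    def __call__(self, x: Tensor) -> Tensor:
        q, k, v = self.form_qkv(x)
        qh, kh, vh = self._split_heads(q), self._split_heads(k), self._split_heads(v)
        # (Q K^T) V computed as Q (K^T V): associativity avoids the N x N
        # score intermediate; with binary spikes all entries are small
        # integers, so the two orders are bit-identical in float32.
        kv = kh.transpose(0, 1, 2, 4, 3) @ vh  # (T, B, h, dk, dk)
        attn = self.lif_attn(self._merge_heads(qh @ kv) * self.scale_s)
        return self.lif_o(self.bn_o(self.w_o(attn)))


class SWSABlock(Module):
    """One encoder block's mixing stage: spiking attention || wavelet branch.

    With ``wavelet_enabled=False`` the block degrades to plain spiking
    self-attention followed by the fusion Linear+BN+LIF (d -> d), which
    is permutation-equivariant over tokens; with the branch enabled the
    spatial token layout matters and that symmetry is intentionally
    broken.
    """

    def __init__(
        self,
        d: int,
        heads: int,
        rng: np.random.Generator,
        wavelet_enabled: bool = True,
        include_hh: bool = False,
        scale_s: float = 0.125,
        lif_cfg: LIFConfig | None = None,
    ):
        self.d = d
        self.wavelet_enabled = wavelet_enabled
        self.attn = SpikingSelfAttention(d, heads, rng, scale_s, lif_cfg)
        self.branch = WaveletBranch(d, rng, include_hh, lif_cfg) if wavelet_enabled else None
        fuse_in = 2 * d if wavelet_enabled else d
        self.fuse_lin = Linear(fuse_in, d, rng)
        self.fuse_bn = BatchNorm(d)
        self.fuse_lif = LIF(lif_cfg)

    def __call__(self, x: Tensor) -> Tensor:
        t, b, n, d = x.shape
        a = self.attn(x)
        if self.branch is not None:
            g = int(round(np.sqrt(n)))
            if g * g != n:
                raise ValueError(f"token count {n} is not a perfect square")
            grid = x.transpose(0, 1, 3, 2).reshape(t, b, d, g, g)
            recon = self.branch(grid)
            recon_tok = recon.reshape(t, b, d, n).transpose(0, 1, 3, 2)
            combined = concat([a, recon_tok], axis=-1)
        else:
            combined = a
        return self.fuse_lif(self.fuse_bn(self.fuse_lin(combined)))
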