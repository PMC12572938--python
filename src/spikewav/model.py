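"""The spiking wavelet transformer: patch-splitting front end, L encoder
blocks (spiking wavelet self-attention + MLP, each with a residual add),
global average pooling and a linear classification head.

Data layout: batches enter as (B, T, C, H, W) float arrays (stacked
encoded windows) and are transposed to the internal time-major layout.
Residual adds operate on spike values, so the residual stream carries
small non-negative integers; there is no LIF after a residual add.  The
classification head is real-valued (no LIF) so cross-entropy on logits
is well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import BatchNorm, Conv2d, LIF, Linear, Module
from .spiking import LIFConfig
from .attention import SWSABlock
from .topomap import EncodedWindow

__all__ = ["ModelConfig", "SpikingWaveletTransformer", "build_model", "stack_windows"]


@dataclass(frozen=True)
class ModelConfig:
    """Desk-scale defaults: T=4 steps, L=2 blocks, d=32, 8x8 token grid."""

    t_steps: int = 4
    n_blocks: int = 2
    d: int = 32
    patch_grid: int = 8
    heads: int = 8
    mlp_ratio: int = 4
    n_classes: int = 2
    in_channels: int = 1
    grid: int = 32
    wavelet_enabled: bool = True
    include_hh: bool = False
    scale_s: float = 0.125
    lif: LIFConfig = field(default_factory=LIFConfig)
    seed: int = 0

    def __post_init__(self):
        if self.t_steps < 1 or self.n_blocks < 1:
            raise ValueError("t_steps and n_blocks must be >= 1")
        if self.d % self.heads:
            raise ValueError(f"d={self.d} not divisible by heads={self.heads}")
        if self.grid % self.patch_grid:
            raise ValueError(f"grid {self.grid} not divisible by patch_grid {self.patch_grid}")
        if self.grid // self.patch_grid not in (1, 2, 4):
            raise ValueError("spatial reduction factor must be 1, 2 or 4 (two conv stages)")
        if self.wavelet_enabled and self.patch_grid % 2:
            raise ValueError("patch_grid must be even for single-level Haar halving")


class SPS(Module):
    """Spiking patch splitting: two conv+BN+LIF stages with downsampling."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        factor = cfg.grid // cfg.patch_grid
        s1, s2 = {1: (1, 1), 2: (2, 1), 4: (2, 2)}[factor]
        mid = max(cfg.d // 2, 1)
        self.conv1 = Conv2d(cfg.in_channels, mid, rng, stride=s1)
        self.bn1 = BatchNorm(mid, channel_axis=1)
        self.lif1 = LIF(cfg.lif)
        self.conv2 = Conv2d(mid, cfg.d, rng, stride=s2)
        self.bn2 = BatchNorm(cfg.d, channel_axis=1)
        self.lif2 = LIF(cfg.lif)
        self.cfg = cfg

    def __call__(self, x: Tensor) -> Tensor:
        """(T, B, C, H, W) -> (T, B, N, d) spike tokens."""
        t, b = x.shape[0], x.shape[1]
        xd = x.data
        replicated = t > 1 and all(np.array_equal(xd[0], xd[i]) for i in range(1, t))
        if replicated:
            # Direct-encoded input is identical across time steps, so the
            # first (pre-spike) conv stage only needs one step's worth of
            # work; BN statistics over B equal those over T*B copies.
            z = self.bn1(self.conv1(x.narrow(0, 0, 1).reshape(b, *x.shape[2:])))
            z = self.lif1(z.expand0(t))
        else:
            flat = x.reshape(t * b, *x.shape[2:])
            z = self.bn1(self.conv1(flat))
            z = self.lif1(z.reshape(t, b, *z.shape[1:]))
        z = self.bn2(self.conv2(z.reshape(t * b, *z.shape[2:])))
        z = self.lif2(z.reshape(t, b, *z.shape[1:]))
        d, gh, gw = z.shape[2:]
        return z.reshape(t, b, d, gh * gw).transpose(0, 1, 3, 2)


class MLPBlock(Module):
    """Linear(d -> r*d) + BN + LIF, Linear(r*d -> d) + BN + LIF."""

    def __init__(self, d: int, ratio: int, rng: np.random.Generator, lif_cfg: LIFConfig):
        self.fc1 = Linear(d, ratio * d, rng)
        self.bn1 = BatchNorm(ratio * d)
        self.lif1 = LIF(lif_cfg)
        self.fc2 = Linear(ratio * d, d, rng)
        self.bn2 = BatchNorm(d)
        self.lif2 = LIF(lif_cfg)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lif2(self.bn2(self.fc2(self.lif1(self.bn1(self.fc1(x))))))


class SpikingWaveletTransformer(Module):
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
        self.sps = SPS(cfg, rng)
        self.blocks = [
            SWSABlock(
                cfg.d, cfg.heads, rng,
                wavelet_enabled=cfg.wavelet_enabled,
                include_hh=cfg.include_hh,
                scale_s=cfg.scale_s,
                lif_cfg=cfg.lif,
            )
            for _ in range(cfg.n_blocks)
        ]
        self.mlps = [MLPBlock(cfg.d, cfg.mlp_ratio, rng, cfg.lif) for _ in range(cfg.n_blocks)]
        self.head = Linear(cfg.d, cfg.n_classes, rng)

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """(B, T, C, H, W) batch -> (B, n_classes) logits Tensor."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 5:
            raise ValueError(f"expected (B, T, C, H, W) input, got shape {x.shape}")
        tokens = self.sps(x.transpose(1, 0, 2, 3, 4))
        for block, mlp in zip(self.blocks, self.mlps):
            tokens = block(tokens) + tokens
            tokens = mlp(tokens) + tokens
        pooled = tokens.mean(axis=2)  # GAP over tokens -> (T, B, d)
        pooled = pooled.mean(axis=0)  # mean over time steps -> (B, d)
        return self.head(pooled)

    __call__ = forward

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax labels; ties break toward the lower class index."""
        from .autodiff import no_grad

        with no_grad():
            scores = self.forward(x).data
        return np.argmax(scores, axis=1)

    def wavelet_coefficients(self) -> list[Tensor]:
        """Analysis coefficients captured in the last forward (for L1 penalty)."""
        return [
            b.branch.last_coeffs
            for b in self.blocks
            if b.branch is not None and b.branch.last_coeffs is not None
        ]

    def attach_recorder(self, recorder: list | None):
        for m in self.modules():
            if isinstance(m, LIF):
                m.recorder = recorder


def build_model(cfg: ModelConfig | None = None) -> SpikingWaveletTransformer:
    return SpikingWaveletTransformer(cfg or ModelConfig())


def stack_windows(windows: list[EncodedWindow]) -> tuple[np.ndarray, np.ndarray]:
    """List of encoded windows -> ((n, T, C, H, W) float32, (n,) int labels)."""
    x = np.stack([w.x for w in windows]).astype(np.float32)
    y = np.array([w.label for w in windows], dtype=np.int64)
    return x, y
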