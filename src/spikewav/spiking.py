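"""Leaky integrate-and-fire (LIF) neuron dynamics and the surrogate gradient.

The LIF neuron integrates input current with a leak toward the reset
potential, emits a binary spike when the membrane potential crosses the
threshold, and hard-resets afterwards:

    H[t] = V[t-1] + (X[t] - (V[t-1] - V_reset)) / tau
    S[t] = Theta(H[t] - V_th)              (Heaviside; 1 for argument >= 0)
    V[t] = H[t] * (1 - S[t]) + V_reset * S[t]

Defaults: threshold 0.5, reset 0, initial potential 0, tau 2 (the membrane
time constant is expressed in simulation steps).  Training replaces the
Heaviside derivative with the derivative of a sharpened sigmoid
(sharpness alpha, default 4); the forward pass stays exactly binary.

This module is the plain-NumPy functional surface; the trainable layer
wrapping the same dynamics lives in :mod:`spikewav.nn`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LIFConfig",
    "LIFState",
    "heaviside",
    "lif_step",
    "lif_sequence",
    "surrogate_gradient",
]


@dataclass(frozen=True)
class LIFConfig:
    """Neuron constants shared by every LIF layer.

    tau is dimensionless (in units of simulation steps) and must be >= 1;
    v_th must exceed v_reset; surrogate_alpha sets the sharpness of the
    sigmoid surrogate used during backpropagation.
    """

    tau: float = 2.0
    v_th: float = 0.5
    v_reset: float = 0.0
    surrogate_alpha: float = 4.0

    def __post_init__(self):
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if not self.v_th > self.v_reset:
            raise ValueError(f"v_th ({self.v_th}) must exceed v_reset ({self.v_reset})")
        if self.surrogate_alpha <= 0:
            raise ValueError("surrogate_alpha must be positive")


@dataclass
class LIFState:
    """Membrane potential of one LIF layer (same shape as the layer)."""

    v: np.ndarray

    @classmethod
    def zeros(cls, shape, v0: float = 0.0, dtype=np.float64) -> "LIFState":
        return cls(np.full(shape, v0, dtype=dtype))


def heaviside(u):
    """Unit step: 1 where u >= 0, else 0 (elementwise)."""
    u = np.asarray(u)
    return (u >= 0).astype(u.dtype if u.dtype.kind == "f" else np.float64)


def lif_step(state: LIFState, x, cfg: LIFConfig) -> tuple[np.ndarray, LIFState]:
    """Advance the membrane one step; return (binary spikes, new state)."""
    x = np.asarray(x, dtype=float)
    if x.shape != state.v.shape:
        raise ValueError(f"input shape {x.shape} does not match state shape {state.v.shape}")
    h = state.v + (x - (state.v - cfg.v_reset)) / cfg.tau
    s = heaviside(h - cfg.v_th)
    v = h * (1.0 - s) + cfg.v_reset * s
    return s, LIFState(v)


def lif_sequence(x_seq, cfg: LIFConfig, initial_v: float = 0.0) -> np.ndarray:
    """Fold :func:`lif_step` over the leading (time) axis of ``x_seq``."""
    x_seq = np.asarray(x_seq, dtype=float)
    if x_seq.shape[0] < 1:
        raise ValueError("need at least one time step")
    state = LIFState.zeros(x_seq.shape[1:], v0=initial_v)
    out = np.empty_like(x_seq)
    for t in range(x_seq.shape[0]):
        out[t], state = lif_step(state, x_seq[t], cfg)
    return out


def surrogate_gradient(u, alpha: float = 4.0):
    """Backward kernel used in place of the Heaviside derivative.

    Returns d/du sigmoid(alpha*u) = alpha * s * (1 - s) with
    s = 1/(1+exp(-alpha*u)).  At u=0, alpha=4 this equals 1.
    """
    u = np.asarray(u, dtype=float)
    s = 1.0 / (1.0 + np.exp(-alpha * u))
    return alpha * s * (1.0 - s)
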