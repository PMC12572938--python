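"""Trainable layers for the spiking transformer, built on :mod:`spikewav.autodiff`.

Conventions
-----------
Token tensors are shaped ``(T, B, N, d)`` (simulation steps, batch, tokens,
embedding); convolutional maps are shaped ``(T*B, C, H, W)`` with time
folded into the batch axis.  Batch normalization computes statistics over
every axis except the channel axis, so it sees all time steps and tokens
at once.  The :class:`LIF` layer iterates over the leading time axis and
keeps its membrane state across those steps only — state is re-created on
every forward call, so two forward passes over the same batch are
bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d
from .spiking import LIFConfig

__all__ = ["Module", "Linear", "Conv2d", "BatchNorm", "LIF", "Adam"]


def _batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple, bshape: tuple):
    """Fused training-mode batch norm with the standard closed-form backward."""
    eps = 1e-5
    xd = x.data
    mean = xd.mean(axis=axes, keepdims=True)
    var = np.square(xd).mean(axis=axes, keepdims=True) - np.square(mean)
    invstd = 1.0 / np.sqrt(var + eps)
    ga = gamma.data.reshape(bshape)
    a = ga * invstd
    b = beta.data.reshape(bshape) - mean * a
    xhat = (xd - mean) * invstd
    out_data = xhat * ga + beta.data.reshape(bshape)
    n = xd.size // mean.size

    def backward(g):
        gbeta = g.sum(axis=axes, keepdims=True)
        ggamma = (g * xhat).sum(axis=axes, keepdims=True)
        gx = a * (g - gbeta / n - xhat * (ggamma / n))
        return (
            gx,
            ggamma.reshape(gamma.shape).astype(gamma.data.dtype),
            gbeta.reshape(beta.shape).astype(beta.data.dtype),
        )

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out, mean.reshape(-1), var.reshape(-1)


def _lif_fused(x: Tensor, cfg: LIFConfig) -> Tensor:
    """LIF dynamics over the leading time axis as one tape node.

    Forward is the exact hard-reset recurrence; backward is truncated-free
    BPTT with the sigmoid surrogate at each Heaviside and the reset term
    detached (gradients do not flow through the reset gate).
    """
    xd = x.data
    t_steps = xd.shape[0]
    inv_tau = 1.0 / cfg.tau
    decay = 1.0 - inv_tau
    bias = cfg.v_reset * inv_tau
    hm = np.empty_like(xd)  # membrane minus threshold, kept for the surrogate
    s = np.empty_like(xd)
    v = None
    for t in range(t_steps):
        ht = hm[t]  # scratch for this step's membrane potential
        np.multiply(xd[t], inv_tau, out=ht)
        if v is not None:
            ht += v
        if bias != 0.0:
            ht += bias
        ht -= cfg.v_th  # store h - v_th directly
        st = s[t]
        st[...] = ht >= 0
        if t + 1 < t_steps:
            # v*decay for the next step, with hard reset (v = 0 where spiked)
            v = (ht + cfg.v_th) * (1.0 - st)
            if cfg.v_reset != 0.0:
                v += cfg.v_reset * st
            v *= decay

    alpha = cfg.surrogate_alpha

    def backward(g):
        gx = np.empty_like(xd)
        gv = None
        for t in reversed(range(t_steps)):
            sig = 1.0 / (1.0 + np.exp(-alpha * hm[t]))
            gh = sig
            gh *= 1.0 - sig
            gh *= alpha
            gh *= g[t]
            if gv is not None:
                gv *= 1.0 - s[t]
                gh += gv
            np.multiply(gh, inv_tau, out=gx[t])
            gh *= decay
            gv = gh
        return (gx,)

    return Tensor._make(s, (x,), backward)


class Module:
    """Base class: parameter discovery by attribute walking."""

    training: bool = True

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    @staticmethod
    def _is_param(val) -> bool:
        # Leaf tensors only: activations cached on modules (e.g. wavelet
        # coefficients from the last forward) carry a tape and are not
        # parameters.
        return isinstance(val, Tensor) and val.requires_grad and val._backward is None

    def parameters(self) -> list[Tensor]:
        params = [v for v in vars(self).values() if Module._is_param(v)]
        for _, child in self._children():
            params.extend(child.parameters())
        return params

    def set_training(self, flag: bool):
        for m in self.modules():
            m.training = flag

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and BN running stats."""
        out = {}
        for mname, mod in self.named_modules():
            for aname, val in vars(mod).items():
                if Module._is_param(val):
                    out[f"{mname}.{aname}" if mname else aname] = val.data
                elif aname.startswith("running_") and isinstance(val, np.ndarray):
                    out[f"{mname}.{aname}" if mname else aname] = val
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        own = self.state_arrays()
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch for keys: {sorted(missing)}")
        for mname, mod in self.named_modules():
            for aname, val in vars(mod).items():
                key = f"{mname}.{aname}" if mname else aname
                if Module._is_param(val):
                    val.data = np.asarray(state[key], dtype=val.data.dtype).reshape(val.data.shape)
                elif aname.startswith("running_") and isinstance(val, np.ndarray):
                    setattr(mod, aname, np.asarray(state[key], dtype=val.dtype).reshape(val.shape))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / np.sqrt(d_in)
        self.w = Tensor(
            rng.uniform(-bound, bound, size=(d_in, d_out)).astype(np.float32), requires_grad=True
        )
        self.b = (
            Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        # Flatten the leading axes so BLAS sees one large GEMM instead of a
        # loop of tiny batched ones.
        lead = x.shape[:-1]
        y = x.reshape(-1, x.shape[-1]) @ self.w
        if self.b is not None:
            y = y + self.b
        return y.reshape(*lead, self.w.shape[1])


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 1,
        padding: int = 1,
        init: str = "kaiming",
    ):
        self.stride, self.padding = stride, padding
        fan_in = c_in * kernel * kernel
        if init == "kaiming":
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        elif init == "zeros":
            w = np.zeros((c_out, c_in, kernel, kernel))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.w = Tensor(w.astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class BatchNorm(Module):
    """Batch normalization over all axes except ``channel_axis``."""

    def __init__(self, num_features: int, channel_axis: int = -1, momentum: float = 0.1):
        self.channel_axis = channel_axis
        self.momentum = momentum
        self.eps = 1e-5
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        ax = self.channel_axis % x.ndim
        axes = tuple(i for i in range(x.ndim) if i != ax)
        bshape = [1] * x.ndim
        bshape[ax] = x.shape[ax]
        if self.training:
            out, mean, var = _batchnorm_train(x, self.gamma, self.beta, axes, tuple(bshape))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        mean = Tensor(self.running_mean.reshape(bshape).astype(x.data.dtype))
        var = Tensor(self.running_var.reshape(bshape).astype(x.data.dtype))
        s = self.gamma.reshape(bshape) / ((var + self.eps) ** 0.5)
        t = self.beta.reshape(bshape) - mean * s
        return x * s + t


class LIF(Module):
    """Multi-step LIF layer over the leading time axis of a Tensor.

    Membrane update per step (hard reset, reset term detached in backward):

        h = v + (x_t - (v - v_reset)) / tau
        s = Heaviside(h - v_th)        # surrogate-sigmoid backward
        v = h * (1 - s) + v_reset * s

    The state is created fresh on every call; spikes are appended to
    ``self.recorder`` (list of arrays) when set, for spike-rate accounting.
    """

    def __init__(self, cfg: LIFConfig | None = None):
        self.cfg = cfg or LIFConfig()
        self.recorder: list | None = None

    def __call__(self, x: Tensor) -> Tensor:
        out = _lif_fused(x, self.cfg)
        if self.recorder is not None:
            self.recorder.append(out.data)
        return out


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
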