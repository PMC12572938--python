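"""Surrogate-gradient training under a cross-entropy objective.

The objective is the batch-mean cross-entropy of the real-valued logits,
optionally plus an L1 penalty on the Haar analysis coefficients captured
during the forward pass (sparsity regularisation of the wavelet
representation; off by default, weight ``lambda_l1``).  Optimisation is
Adam at the stated initial learning rate of 1e-4 with no schedule.

Runs are reproducible: the train/validation split, per-epoch shuffling
and parameter initialisation each draw from dedicated streams derived
from the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .model import SpikingWaveletTransformer
from .nn import Adam

__all__ = ["TrainConfig", "TrainHistory", "EvalResult", "loss", "train", "evaluate",
           "train_test_split"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 30  # desk-scale default; the reference setting is 200
    batch_size: int = 16
    seed: int = 0
    lambda_l1: float = 0.0
    optimizer: str = "adam"
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1 or self.lambda_l1 < 0:
            raise ValueError("need lr > 0, epochs >= 1, lambda_l1 >= 0")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    spike_rate: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "train_acc": self.train_acc,
            "val_acc": self.val_acc,
            "spike_rate": self.spike_rate,
        }


@dataclass
class EvalResult:
    accuracy: float
    per_class: dict[int, float]
    spike_rate: float


def loss(
    scores: Tensor,
    labels: np.ndarray,
    wavelet_coeffs: list[Tensor] | None = None,
    lambda_l1: float = 0.0,
) -> Tensor:
    """Mean cross-entropy over the batch (+ optional wavelet L1 penalty)."""
    labels = np.asarray(labels)
    n, k = scores.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"label out of range [0, {k}) in {np.unique(labels)}")
    m = scores.data.max(axis=1, keepdims=True)  # constant shift for stability
    z = scores - m
    logp = z - z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros((n, k), dtype=scores.data.dtype)
    onehot[np.arange(n), labels] = 1.0
    out = -(logp * onehot).sum() * (1.0 / n)
    if lambda_l1 > 0 and wavelet_coeffs:
        penalty = wavelet_coeffs[0].abs().sum()
        for c in wavelet_coeffs[1:]:
            penalty = penalty + c.abs().sum()
        out = out + lambda_l1 * penalty
    return out


def train_test_split(
    x: np.ndarray, y: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified split; deterministic in seed."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    test_idx = []
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        rng.shuffle(idx)
        test_idx.extend(idx[: int(round(test_fraction * len(idx)))])
    mask = np.zeros(len(y), dtype=bool)
    mask[test_idx] = True
    return x[~mask], y[~mask], x[mask], y[mask]


def _spike_stats(model: SpikingWaveletTransformer):
    class _Counter(list):
        ones = 0.0
        total = 0.0

        def append(self, arr):
            self.ones += float(arr.sum())
            self.total += float(arr.size)

    rec = _Counter()
    model.attach_recorder(rec)
    return rec


def evaluate(
    model: SpikingWaveletTransformer, x: np.ndarray, y: np.ndarray, batch_size: int = 64
) -> EvalResult:
    """Accuracy, per-class accuracy and mean spiking rate over one pass."""
    if len(y) == 0:
        raise ValueError("empty evaluation dataset")
    model.set_training(False)
    rec = _spike_stats(model)
    preds = np.concatenate(
        [model.predict(x[i : i + batch_size]) for i in range(0, len(y), batch_size)]
    )
    model.attach_recorder(None)
    model.set_training(True)
    per_class = {
        int(c): float(np.mean(preds[y == c] == c)) for c in np.unique(y)
    }
    rate = rec.ones / rec.total if rec.total else 0.0
    return EvalResult(float(np.mean(preds == y)), per_class, float(rate))


def train(
    model: SpikingWaveletTransformer,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> tuple[SpikingWaveletTransformer, TrainHistory]:
    """Fit in place; returns the model and its per-epoch history."""
    if len(y) == 0:
        raise ValueError("empty training dataset")
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if cfg.val_fraction > 0:
        x_tr, y_tr, x_val, y_val = train_test_split(x, y, cfg.val_fraction, cfg.seed)
    else:
        x_tr, y_tr, x_val, y_val = x, y, x[:0], y[:0]
    opt = Adam(model.parameters(), lr=cfg.lr)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 13)))
    history = TrainHistory()
    n = len(y_tr)
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            opt.zero_grad()
            scores = model.forward(xb)
            coeffs = model.wavelet_coefficients() if cfg.lambda_l1 > 0 else None
            batch_loss = loss(scores, yb, coeffs, cfg.lambda_l1)
            if not np.isfinite(batch_loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size} "
                    f"(lr={cfg.lr})"
                )
            batch_loss.backward()
            opt.step()
            losses.append(float(batch_loss.data))
            correct += int(np.sum(np.argmax(scores.data, axis=1) == yb))
        history.train_loss.append(float(np.mean(losses)))
        history.train_acc.append(correct / n)
        if len(y_val):
            res = evaluate(model, x_val, y_val)
            history.val_acc.append(res.accuracy)
            history.spike_rate.append(res.spike_rate)
        else:
            history.val_acc.append(float("nan"))
            history.spike_rate.append(float("nan"))
        log.info(
            "epoch %3d  loss %.4f  train_acc %.3f  val_acc %s",
            epoch, history.train_loss[-1], history.train_acc[-1],
            f"{history.val_acc[-1]:.3f}" if len(y_val) else "n/a",
        )
    return model, history
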