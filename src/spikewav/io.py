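"""HDF5 container I/O for recordings, encoded datasets and model checkpoints.

Container layout (one file can hold either or both groups):

    /data                (n_channels, n_samples) float64
    /fs                  scalar
    /montage/names       variable-length strings
    /montage/pos         (n_channels, 2)
    /trials              (n_trials, 3) int64 rows (start, end, label)
    /encoded/x           (n, T, C, H, W) float32
    /encoded/y           (n,) int64

Checkpoints store the flattened parameter arrays plus the model config as
a JSON attribute, so a model can be rebuilt and reloaded exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile

import h5py
import numpy as np

from .model import ModelConfig, SpikingWaveletTransformer, build_model
from .spiking import LIFConfig
from .synth import EEGRecording, Montage

__all__ = [
    "save_recording", "load_recording", "save_encoded", "load_encoded",
    "save_checkpoint", "load_checkpoint",
]


def _atomic_h5(path: str, writer):
    """Write to a temp file in the target directory, then replace."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(suffix=".h5", dir=d)
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            writer(f)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def save_recording(path: str, rec: EEGRecording):
    def writer(f: h5py.File):
        f.create_dataset("data", data=rec.data)
        f.create_dataset("fs", data=float(rec.fs))
        g = f.create_group("montage")
        g.create_dataset("names", data=list(rec.montage.channel_names),
                         dtype=h5py.string_dtype())
        g.create_dataset("pos", data=rec.montage.positions)
        f.create_dataset("trials", data=np.array(rec.trials, dtype=np.int64))

    _atomic_h5(path, writer)


def load_recording(path: str) -> EEGRecording:
    with h5py.File(path, "r") as f:
        names = tuple(n.decode() if isinstance(n, bytes) else n for n in f["montage/names"][()])
        montage = Montage(names, f["montage/pos"][()])
        trials = [tuple(int(v) for v in row) for row in f["trials"][()]]
        return EEGRecording(f["data"][()], float(f["fs"][()]), montage, trials)


def save_encoded(path: str, x: np.ndarray, y: np.ndarray):
    def writer(f: h5py.File):
        g = f.create_group("encoded")
        g.create_dataset("x", data=np.asarray(x, dtype=np.float32))
        g.create_dataset("y", data=np.asarray(y, dtype=np.int64))

    _atomic_h5(path, writer)


def load_encoded(path: str) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        return f["encoded/x"][()], f["encoded/y"][()]


def _config_to_json(cfg: ModelConfig) -> str:
    d = dataclasses.asdict(cfg)
    return json.dumps(d)


def _config_from_json(blob: str) -> ModelConfig:
    d = json.loads(blob)
    d["lif"] = LIFConfig(**d["lif"])
    return ModelConfig(**d)


def save_checkpoint(path: str, model: SpikingWaveletTransformer):
    state = model.state_arrays()

    def writer(f: h5py.File):
        f.attrs["config"] = _config_to_json(model.cfg)
        g = f.create_group("state")
        for k, v in state.items():
            g.create_dataset(k, data=v)

    _atomic_h5(path, writer)


def load_checkpoint(path: str) -> SpikingWaveletTransformer:
    with h5py.File(path, "r") as f:
        model = build_model(_config_from_json(f.attrs["config"]))
        state = {k: f["state"][k][()] for k in f["state"]}
    model.load_state_arrays(state)
    return model
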