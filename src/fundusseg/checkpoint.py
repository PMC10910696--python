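"""Checkpoint archives: a single ``.npz`` with weights, config and a version tag."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import ModelConfig, SegNet

FORMAT_VERSION = "fundusseg-ckpt-1"

__all__ = ["save_checkpoint", "load_checkpoint", "load_model", "FORMAT_VERSION"]


def save_checkpoint(path, module, config: dict, extra: dict | None = None):
    """Serialize a module's parameters plus a JSON config blob."""
    meta = {"version": FORMAT_VERSION, "config": config, "extra": extra or {}}
    state = {f"param/{k}": v for k, v in module.state_dict().items()}
    with open(Path(path), "wb") as f:  # exact path; no implicit .npz suffix
        np.savez(f, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    """Return ``(state_dict, config, extra)`` from a checkpoint archive."""
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    return state, meta["config"], meta["extra"]


def load_model(path) -> SegNet:
    """Rebuild a :class:`SegNet` from a checkpoint written by the trainer."""
    state, config, _ = load_checkpoint(path)
    model = SegNet(ModelConfig.from_dict(config))
    model.load_state_dict(state)
    return model
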