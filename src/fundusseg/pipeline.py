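"""End-to-end orchestration: supervised training, evaluation, prediction.

Supervised training optimizes the rim-constrained multi-label loss with Adam
at batch size 1 (group normalization in the encoder keeps single-image
statistics well-defined).  Defaults follow the full-scale recipe — 100
epochs, learning rate 1e-4 decaying ×0.1 every 50 epochs — while
``max_steps`` supports short desk-scale runs.  A held-out validation split
(default 20% of the manifest, seed-controlled) selects the best checkpoint
by validation loss.

All randomness flows through explicit seeds; fixed-seed reruns reproduce
logs and integer-valued outputs exactly.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize as _sk_resize

from . import nn
from .checkpoint import load_model, save_checkpoint
from .losses import rim_loss
from .metrics import evaluate_masks
from .model import ModelConfig, SegNet
from .ssl import transfer_weights
from .synthetic import FundusImage, encode_mask_png, load_manifest, load_sample

__all__ = ["TrainConfig", "train", "evaluate", "predict"]


@dataclass
class TrainConfig:
    epochs: int = 100
    lr: float = 1e-4
    lr_decay_every: int = 50
    lr_decay_factor: float = 0.1
    batch_size: int = 1
    eps: float = 1e-6
    val_fraction: float = 0.2
    seed: int = 0
    max_steps: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _load_labeled(manifest_path):
    manifest = load_manifest(manifest_path)
    samples = [load_sample(manifest_path, e) for e in manifest["samples"]]
    missing = [s.id for s in samples if s.disc_mask is None]
    if missing:
        raise ValueError(f"manifest entries without masks: {missing[:5]}")
    return samples


def _image_loss(model: SegNet, sample: FundusImage, eps: float):
    out = model(sample)
    return rim_loss(out.p_disc[0], out.p_cup[0], sample.disc_mask,
                    sample.cup_mask, eps=eps)


def _val_scores(model: SegNet, samples, eps: float):
    losses, f1d, f1c = [], [], []
    for s in samples:
        losses.append(float(_image_loss(model, s, eps).data))
        disc, cup, _ = model.predict_masks(s)
        rep = evaluate_masks(disc, cup, s.disc_mask, s.cup_mask)
        f1d.append(rep.disc["f1"])
        f1c.append(rep.cup["f1"])
    return float(np.mean(losses)), float(np.mean(f1d)), float(np.mean(f1c))


def train(manifest_path, out_ckpt, config: TrainConfig | None = None,
          model_config: ModelConfig | None = None, init=None,
          log_path=None) -> list[dict]:
    """Train the segmentation network on a labeled manifest.

    ``init`` may name an SSL checkpoint whose encoder weights initialize the
    network.  Writes the best-validation-loss checkpoint to ``out_ckpt`` and
    returns the per-epoch log (also written as CSV when ``log_path`` given).
    """
    config = config or TrainConfig()
    model_config = model_config or ModelConfig()
    samples = _load_labeled(manifest_path)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(samples))
    n_val = max(1, int(round(config.val_fraction * len(samples)))) \
        if len(samples) > 1 else 0
    val = [samples[i] for i in order[:n_val]]
    tr = [samples[i] for i in order[n_val:]]

    model = SegNet(model_config)
    init_report = None
    if init is not None:
        init_report = transfer_weights(init, model)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    sched = nn.StepDecay(opt, config.lr, config.lr_decay_every,
                         config.lr_decay_factor)

    log: list[dict] = []
    best_val = np.inf
    best_state = model.state_dict()
    steps_done = 0
    for epoch in range(config.epochs):
        sched.set_epoch(epoch)
        losses = []
        for i in rng.permutation(len(tr)):
            loss = _image_loss(model, tr[i], config.eps)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            steps_done += 1
            if config.max_steps is not None and steps_done >= config.max_steps:
                break
        if val:
            val_loss, val_f1_disc, val_f1_cup = _val_scores(model, val, config.eps)
        else:
            val_loss, val_f1_disc, val_f1_cup = float("nan"), float("nan"), float("nan")
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_loss": val_loss, "val_f1_disc": val_f1_disc,
                    "val_f1_cup": val_f1_cup})
        if not val or val_loss <= best_val:
            best_val = val_loss if val else -np.inf
            best_state = model.state_dict()
        if config.max_steps is not None and steps_done >= config.max_steps:
            break

    model.load_state_dict(best_state)
    save_checkpoint(out_ckpt, model, model_config.to_dict(),
                    extra={"kind": "segnet", "train_config": config.to_dict(),
                           "init": bool(init),
                           "transferred": len(init_report["transferred"])
                           if init_report else 0})
    if log_path is not None:
        with open(log_path, "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=list(log[0].keys()))
            w.writeheader()
            w.writerows(log)
    return log


def evaluate(checkpoint_path, manifest_path, out_csv=None) -> pd.DataFrame:
    """Per-image metrics plus a mean row for a labeled manifest."""
    model = load_model(checkpoint_path)
    samples = _load_labeled(manifest_path)
    rows = []
    for s in samples:
        disc, cup, _ = model.predict_masks(s)
        rep = evaluate_masks(disc, cup, s.disc_mask, s.cup_mask)
        row = {"id": s.id}
        row.update(rep.flat())
        row["cdr_abs_err"] = abs(rep.cdr_pred - rep.cdr_gt) \
            if np.isfinite(rep.cdr_pred) else float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns=["id"]).mean(numeric_only=True)
    mean_row["id"] = "mean"
    df = pd.concat([df, mean_row.to_frame().T[df.columns]], ignore_index=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def _round32(x: int) -> int:
    return max(32, int(round(x / 32)) * 32)


def predict(checkpoint_path, image_path, out_path, clip_cup: bool = False) -> dict:
    """Segment one image file and write the 3-level mask PNG (0/128/255).

    Inputs whose sizes are not multiples of 32 are resized for inference and
    the probability maps are resized back before thresholding, so the output
    mask matches the input resolution.  Deterministic and idempotent.
    """
    arr = iio.imread(image_path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    img = arr[..., :3].astype(np.float32) / 255.0
    h, w = img.shape[:2]
    h32, w32 = _round32(h), _round32(w)
    net_in = img if (h, w) == (h32, w32) else _sk_resize(
        img, (h32, w32), order=1, preserve_range=True, anti_aliasing=False
    ).astype(np.float32)

    model = load_model(checkpoint_path)
    p_disc, p_cup = model(net_in).numpy()
    if (h, w) != (h32, w32):
        p_disc = _sk_resize(p_disc, (h, w), order=1, preserve_range=True)
        p_cup = _sk_resize(p_cup, (h, w), order=1, preserve_range=True)
    thr = model.config.threshold
    from .model import _largest_component
    disc = _largest_component(p_disc > thr)
    cup = _largest_component(p_cup > thr)
    if clip_cup:
        cup = cup & disc
    iio.imwrite(Path(out_path), encode_mask_png(disc, cup))
    return {"disc_pixels": int(disc.sum()), "cup_pixels": int(cup.sum()),
            "empty_disc": not disc.any(), "empty_cup": not cup.any()}
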