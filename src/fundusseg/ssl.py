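"""Contrastive self-supervised pretraining of the encoder.

Two independently augmented views of each unlabeled image are encoded by the
shared (siamese) encoder; the deepest feature map is pooled to a fixed
24×24 grid (full-image-box RoiAlign realized as bilinear sampling at two
points per bin), flattened, projected by a fully connected layer to a
128-dimensional embedding and L2-normalized.  The InfoNCE objective with
in-batch negatives (K = 2·(batch−1)) pulls the two views of an image
together and pushes all other views in the mini-batch apart.

Augmentations (each parameter drawn uniformly from its range, in a fixed
order: rotation → sharpen → gamma → blur):

====================  =======================
rotation              0°, 90°, 180°, 270°
sharpen alpha-blend   α ∈ [0, 1]
gamma contrast        γ ∈ [0.5, 2.0]
Gaussian blur         σ ∈ [0, 0.5]
====================  =======================

Defaults follow the pretraining recipe: 30 epochs, Adam at 1e-4 decaying
×0.1 every 15 epochs, batch size 8.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import nn
from .checkpoint import load_checkpoint, save_checkpoint
from .losses import info_nce_batch
from .model import ModelConfig, SegNet
from .nn import Tensor
from .synthetic import load_manifest, load_sample

__all__ = [
    "AugmentationConfig",
    "ViewPair",
    "ProjectionHead",
    "PretrainConfig",
    "augment_view",
    "contrastive_embed",
    "pretrain",
    "transfer_weights",
]

_ENCODER_PREFIXES = ("stem.", "stage1.", "stage2.", "stage3.", "stage4.",
                     "attn.", "agg.")


@dataclass
class AugmentationConfig:
    rotation_choices: tuple[int, ...] = (0, 90, 180, 270)
    sharpen_alpha_range: tuple[float, float] = (0.0, 1.0)
    gamma_range: tuple[float, float] = (0.5, 2.0)
    blur_sigma_range: tuple[float, float] = (0.0, 0.5)
    order: tuple[str, ...] = ("rotation", "sharpen", "gamma", "blur")


@dataclass
class ViewPair:
    view_a: np.ndarray
    view_b: np.ndarray
    source_id: str


def sample_augment_params(config: AugmentationConfig, rng: np.random.Generator) -> dict:
    """Draw one set of augmentation parameters (always within the ranges)."""
    return {
        "rotation": int(rng.choice(config.rotation_choices)),
        "alpha": float(rng.uniform(*config.sharpen_alpha_range)),
        "gamma": float(rng.uniform(*config.gamma_range)),
        "sigma": float(rng.uniform(*config.blur_sigma_range)),
    }


def apply_augment(image: np.ndarray, params: dict,
                  order=("rotation", "sharpen", "gamma", "blur")) -> np.ndarray:
    out = np.asarray(image, dtype=np.float32)
    for step in order:
        if step == "rotation":
            out = np.rot90(out, k=params["rotation"] // 90, axes=(0, 1))
        elif step == "sharpen":
            a = params["alpha"]
            if a > 0:
                blurred = gaussian_filter(out, sigma=(1.0, 1.0, 0.0))
                out = out + np.float32(a) * (out - blurred)
        elif step == "gamma":
            out = np.clip(out, 0.0, 1.0) ** np.float32(params["gamma"])
        elif step == "blur":
            s = params["sigma"]
            if s > 1e-8:
                out = gaussian_filter(out, sigma=(s, s, 0.0))
        else:
            raise ValueError(f"unknown augmentation step {step!r}")
    return np.ascontiguousarray(np.clip(out, 0.0, 1.0), dtype=np.float32)


def augment_view(image: np.ndarray, config: AugmentationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """One randomly augmented view; deterministic given the rng state."""
    return apply_augment(image, sample_augment_params(config, rng), config.order)


class ProjectionHead(nn.Module):
    """RoiAlign-pooled global feature → standardize → FC → unit-norm embedding.

    The flattened pooled feature is standardized across the mini-batch
    (batch-norm style, running statistics at inference) before the single
    fully connected projection.  Deep features of distinct images share a
    large common component; without the centering, all embeddings collapse
    onto that direction and the contrastive objective carries no signal.
    """

    def __init__(self, in_channels: int, rng: np.random.Generator,
                 pooled_size: int = 24, embed_dim: int = 128,
                 momentum: float = 0.1, eps: float = 1e-5,
                 standardize: bool = False):
        super().__init__()
        self.pooled_size = pooled_size
        self.embed_dim = embed_dim
        self.in_channels = in_channels
        self.momentum = momentum
        self.eps = eps
        self.standardize = standardize
        dim = in_channels * pooled_size * pooled_size
        self.fc = nn.Linear(dim, embed_dim, rng)
        self.register_buffer("running_mean", np.zeros(dim, dtype=np.float32))
        self.register_buffer("running_var", np.ones(dim, dtype=np.float32))

    def pool(self, feature_map: Tensor) -> Tensor:
        """Full-image-box RoiAlign: 2×2 bilinear samples per output bin."""
        s = self.pooled_size
        fine = nn.interpolate_bilinear(feature_map, 2 * s, 2 * s)
        return nn.avg_pool2d(fine, 2)

    def pool_flat(self, feature_map: Tensor) -> Tensor:
        b = feature_map.shape[0]
        return self.pool(feature_map).reshape(b, -1)

    def project(self, flat: Tensor, train: bool = False) -> Tensor:
        """Standardize, project and L2-normalize a (B, dim) pooled batch."""
        if self.standardize and train and flat.shape[0] > 1:
            mu = flat.mean(axis=0, keepdims=True)
            var = ((flat - mu) ** 2).mean(axis=0, keepdims=True)
            m = self.momentum
            self._set_buffer("running_mean",
                             (1 - m) * self.running_mean + m * mu.data[0])
            self._set_buffer("running_var",
                             (1 - m) * self.running_var + m * var.data[0])
            xhat = (flat - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (flat - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        z = self.fc(xhat)
        norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12) ** -0.5
        return z * norm

    def forward(self, feature_map: Tensor, train: bool = False) -> Tensor:
        return self.project(self.pool_flat(feature_map), train=train)


def contrastive_embed(image, encoder: SegNet, head: ProjectionHead) -> Tensor:
    """Embed one image (or batch) through encoder F4 and the projection head."""
    feats = encoder.encode(image)
    return head(feats.f4)


@dataclass
class PretrainConfig:
    epochs: int = 30
    lr: float = 1e-4
    lr_decay_every: int = 15
    lr_decay_factor: float = 0.1
    batch_size: int = 8
    tau: float = 0.07
    embed_dim: int = 128
    standardize_head: bool = False
    seed: int = 0
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)


def pretrain(manifest_path, out_path, config: PretrainConfig | None = None,
             model_config: ModelConfig | None = None,
             log_path=None) -> list[dict]:
    """Contrastive pretraining on an unlabeled manifest; writes a checkpoint.

    Returns the loss log: one record per optimizer step with epoch, step and
    loss.  Fully reproducible for a fixed config seed.
    """
    config = config or PretrainConfig()
    model_config = model_config or ModelConfig()
    manifest = load_manifest(manifest_path)
    entries = manifest["samples"]
    if not entries:
        raise ValueError("empty manifest")
    if len(entries) < config.batch_size:
        raise ValueError(
            f"need at least {config.batch_size} images, got {len(entries)}")
    images = [load_sample(manifest_path, e).pixels for e in entries]

    model = SegNet(model_config)
    rng = np.random.default_rng(config.seed)
    head = ProjectionHead(model.config.stage_widths[3],
                          np.random.default_rng(rng.integers(2 ** 31)),
                          embed_dim=config.embed_dim,
                          standardize=config.standardize_head)
    opt = nn.Adam(list(model.parameters()) + list(head.parameters()), lr=config.lr)
    sched = nn.StepDecay(opt, config.lr, config.lr_decay_every, config.lr_decay_factor)

    log: list[dict] = []
    n = len(images)
    steps = n // config.batch_size
    for epoch in range(config.epochs):
        sched.set_epoch(epoch)
        order = rng.permutation(n)
        for step in range(steps):
            idx = order[step * config.batch_size:(step + 1) * config.batch_size]
            flats_a, flats_b = [], []
            for i in idx:
                for bucket in (flats_a, flats_b):
                    view = augment_view(images[i], config.augment, rng)
                    bucket.append(head.pool_flat(model.encode(view).f4))
            z = head.project(nn.concat(flats_a + flats_b, axis=0), train=True)
            nb = len(idx)
            loss = info_nce_batch(z[:nb], z[nb:], tau=config.tau)
            opt.zero_grad()
            loss.backward()
            opt.step()
            log.append({"epoch": epoch, "step": step, "loss": float(loss.data)})

    extra = {"head_config": {"pooled_size": head.pooled_size,
                             "embed_dim": head.embed_dim,
                             "in_channels": head.in_channels,
                             "standardize": head.standardize},
             "kind": "ssl"}
    class _Joint(nn.Module):
        def __init__(self):
            super().__init__()
            self.model = model
            self.head = head
    save_checkpoint(out_path, _Joint(), model_config.to_dict(), extra=extra)
    if log_path is not None:
        with open(log_path, "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=["epoch", "step", "loss"])
            w.writeheader()
            w.writerows(log)
    return log


def load_pretrained(path) -> tuple[SegNet, ProjectionHead]:
    """Rebuild the SSL model + projection head from a pretraining checkpoint."""
    state, config, extra = load_checkpoint(path)
    model = SegNet(ModelConfig.from_dict(config))
    hc = extra["head_config"]
    head = ProjectionHead(hc["in_channels"], np.random.default_rng(0),
                          pooled_size=hc["pooled_size"], embed_dim=hc["embed_dim"],
                          standardize=hc.get("standardize", False))
    model.load_state_dict({k[len("model."):]: v for k, v in state.items()
                           if k.startswith("model.")})
    head.load_state_dict({k[len("head."):]: v for k, v in state.items()
                          if k.startswith("head.")})
    return model, head


def transfer_weights(ssl_checkpoint_path, segnet: SegNet) -> dict:
    """Copy encoder weights from an SSL checkpoint into a segmentation net.

    The decoder and head keep their fresh initialization.  Returns a report
    with ``transferred`` and ``skipped`` parameter names; raises on encoder
    shape mismatches, listing the offending layers.
    """
    state, _, _ = load_checkpoint(ssl_checkpoint_path)
    enc_state = {k[len("model."):]: v for k, v in state.items()
                 if k.startswith("model.")}
    own = dict(segnet.named_parameters())
    transferred, skipped, bad = [], [], []
    for name, p in own.items():
        if not name.startswith(_ENCODER_PREFIXES):
            skipped.append(name)
            continue
        if name not in enc_state:
            bad.append(f"{name}: missing from checkpoint")
            continue
        src = enc_state[name]
        if src.shape != p.data.shape:
            bad.append(f"{name}: {src.shape} vs {p.data.shape}")
            continue
        p.data = np.asarray(src, dtype=np.float32).copy()
        transferred.append(name)
    if bad:
        raise ValueError("incompatible encoder configuration:\n  " + "\n  ".join(bad))
    return {"transferred": transferred, "skipped": skipped}
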