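"""Synthetic fundus-like image generator with exact disc/cup ground truth.

Real fundus photographs show a bright elliptical optic disc containing a
brighter elliptical optic cup on a textured red-orange retina, crossed by
dark curvilinear blood vessels.  This module renders that geometry with
known ellipse parameters so the segmentation network, the losses and the
metrics can all be exercised with exact ground truth and no data downloads.

The cup ellipse is guaranteed to lie inside the disc ellipse (checked
analytically at generation time), mirroring the anatomical containment
constraint the rim loss exploits.  Generation is fully deterministic given
the scene parameters, including their seed.

Mask PNG convention: 0 = background, 128 = disc outside the cup, 255 = cup
(which is always also disc).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneParams",
    "FundusImage",
    "InvalidGeometryError",
    "make_sample",
    "make_dataset",
    "load_manifest",
    "load_sample",
    "encode_mask_png",
    "decode_mask_png",
]

# Rendering palette (RGB in [0, 1]); green channel is ordered
# background < disc < cup, as in real fundus contrast.
_BACKGROUND_RGB = (0.55, 0.30, 0.10)
_DISC_RGB = (0.93, 0.62, 0.33)
_CUP_RGB = (0.99, 0.80, 0.45)
_VESSEL_RGB = (0.35, 0.10, 0.06)


class InvalidGeometryError(ValueError):
    """Raised when the cup ellipse would cross the disc boundary or the canvas."""


@dataclass
class SceneParams:
    """Parameters of one synthetic scene.

    ``disc_axes`` are the (semi-major, semi-minor) ellipse semi-axes in pixels;
    ``cup_scale`` multiplies both disc axes to give the cup axes;
    ``cup_offset`` shifts the cup center relative to the disc center and must
    keep the cup inside the disc.  Coordinates are (row, col), 0-based, with
    pixel centers at integer coordinates.
    """

    image_size: int = 128
    disc_center: tuple[float, float] = (64.0, 64.0)
    disc_axes: tuple[float, float] = (28.0, 24.0)
    disc_rotation: float = 0.0
    cup_scale: float = 0.4
    cup_offset: tuple[float, float] = (0.0, 0.0)
    vessel_count: int = 6
    noise_sd: float = 0.02
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["disc_center"] = [float(v) for v in self.disc_center]
        d["disc_axes"] = [float(v) for v in self.disc_axes]
        d["cup_offset"] = [float(v) for v in self.cup_offset]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        d = dict(d)
        for key in ("disc_center", "disc_axes", "cup_offset"):
            d[key] = tuple(float(v) for v in d[key])
        return cls(**d)


@dataclass
class FundusImage:
    """An RGB raster with optional paired disc/cup ground-truth masks."""

    pixels: np.ndarray                      # H×W×3 float32 in [0, 1]
    disc_mask: np.ndarray | None = None     # H×W bool
    cup_mask: np.ndarray | None = None      # H×W bool
    id: str = ""

    def __post_init__(self):
        if self.disc_mask is not None and self.disc_mask.shape != self.pixels.shape[:2]:
            raise ValueError("disc mask size differs from image size")
        if self.cup_mask is not None:
            if self.cup_mask.shape != self.pixels.shape[:2]:
                raise ValueError("cup mask size differs from image size")
            if self.disc_mask is not None and np.any(self.cup_mask & ~self.disc_mask):
                raise ValueError("cup mask has pixels outside the disc mask")


def _ellipse_mask(size: int, center, axes, rotation_deg: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    th = np.deg2rad(rotation_deg)
    dr = rr - center[0]
    dc = cc - center[1]
    u = np.cos(th) * dr + np.sin(th) * dc
    v = -np.sin(th) * dr + np.cos(th) * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _cup_geometry(p: SceneParams):
    center = (p.disc_center[0] + p.cup_offset[0], p.disc_center[1] + p.cup_offset[1])
    axes = (p.cup_scale * p.disc_axes[0], p.cup_scale * p.disc_axes[1])
    return center, axes


def _check_geometry(p: SceneParams):
    if not (0.0 < p.cup_scale < 1.0):
        raise InvalidGeometryError(f"cup_scale must be in (0,1), got {p.cup_scale}")
    if min(p.disc_axes) <= 0:
        raise InvalidGeometryError("disc axes must be positive")
    th = np.deg2rad(p.disc_rotation)
    angles = np.linspace(0.0, 2 * np.pi, 721)
    # disc boundary must fit on the canvas
    br = (p.disc_center[0] + p.disc_axes[0] * np.cos(angles) * np.cos(th)
          - p.disc_axes[1] * np.sin(angles) * np.sin(th))
    bc = (p.disc_center[1] + p.disc_axes[0] * np.cos(angles) * np.sin(th)
          + p.disc_axes[1] * np.sin(angles) * np.cos(th))
    if br.min() < 0 or bc.min() < 0 or br.max() > p.image_size - 1 or bc.max() > p.image_size - 1:
        raise InvalidGeometryError("disc ellipse does not fit inside the canvas")
    # every cup boundary point must lie inside the disc ellipse
    cc_center, cc_axes = _cup_geometry(p)
    pr = (cc_center[0] + cc_axes[0] * np.cos(angles) * np.cos(th)
          - cc_axes[1] * np.sin(angles) * np.sin(th))
    pc = (cc_center[1] + cc_axes[0] * np.cos(angles) * np.sin(th)
          + cc_axes[1] * np.sin(angles) * np.cos(th))
    dr = pr - p.disc_center[0]
    dc = pc - p.disc_center[1]
    u = np.cos(th) * dr + np.sin(th) * dc
    v = -np.sin(th) * dr + np.cos(th) * dc
    if np.any((u / p.disc_axes[0]) ** 2 + (v / p.disc_axes[1]) ** 2 > 1.0):
        raise InvalidGeometryError("cup ellipse crosses the disc boundary")


def _draw_vessels(img: np.ndarray, p: SceneParams, rng: np.random.Generator):
    """Dark quadratic Bézier-like curves converging near the disc, as distractors."""
    size = p.image_size
    vmask = np.zeros((size, size), dtype=bool)
    for _ in range(p.vessel_count):
        side = rng.integers(0, 4)
        t_edge = rng.uniform(0, size - 1)
        p0 = [(0.0, t_edge), (size - 1.0, t_edge), (t_edge, 0.0), (t_edge, size - 1.0)][side]
        p2 = (p.disc_center[0] + rng.uniform(-0.5, 0.5) * p.disc_axes[0] * 2,
              p.disc_center[1] + rng.uniform(-0.5, 0.5) * p.disc_axes[1] * 2)
        p1 = ((p0[0] + p2[0]) / 2 + rng.uniform(-0.25, 0.25) * size,
              (p0[1] + p2[1]) / 2 + rng.uniform(-0.25, 0.25) * size)
        width = rng.uniform(0.8, 1.8)
        t = np.linspace(0.0, 1.0, 4 * size)[:, None]
        pts = ((1 - t) ** 2 * np.array(p0) + 2 * t * (1 - t) * np.array(p1)
               + t ** 2 * np.array(p2))
        for dr in (-width / 2, 0.0, width / 2):
            for dc in (-width / 2, 0.0, width / 2):
                r = np.clip(np.round(pts[:, 0] + dr).astype(int), 0, size - 1)
                c = np.clip(np.round(pts[:, 1] + dc).astype(int), 0, size - 1)
                vmask[r, c] = True
    alpha = gaussian_filter(vmask.astype(np.float32), 0.6)
    alpha = np.clip(alpha * 1.5, 0.0, 0.9)[..., None]
    img[:] = img * (1 - alpha) + np.asarray(_VESSEL_RGB, dtype=np.float32) * alpha


def make_sample(params: SceneParams) -> FundusImage:
    """Render one synthetic fundus scene with exact disc/cup masks.

    Raises :class:`InvalidGeometryError` if the cup would cross the disc
    boundary or the disc the canvas.  Bit-identical for identical params.
    """
    _check_geometry(params)
    size = params.image_size
    rng = np.random.default_rng(params.seed)

    disc_mask = _ellipse_mask(size, params.disc_center, params.disc_axes,
                              params.disc_rotation)
    cup_center, cup_axes = _cup_geometry(params)
    cup_mask = _ellipse_mask(size, cup_center, cup_axes, params.disc_rotation)
    cup_mask &= disc_mask  # rasterization safety; analytic check already passed

    img = np.empty((size, size, 3), dtype=np.float32)
    img[:] = np.asarray(_BACKGROUND_RGB, dtype=np.float32)
    texture = gaussian_filter(rng.normal(0.0, 1.0, (size, size)).astype(np.float32), size / 16)
    texture *= 0.5 / max(np.abs(texture).max(), 1e-8)
    img += texture[..., None] * np.array([0.12, 0.07, 0.03], dtype=np.float32)

    # soft-edged structures for rendering only; masks stay exact
    disc_soft = gaussian_filter(disc_mask.astype(np.float32), 1.0)[..., None]
    cup_soft = gaussian_filter(cup_mask.astype(np.float32), 1.0)[..., None]
    img = img * (1 - disc_soft) + np.asarray(_DISC_RGB, dtype=np.float32) * disc_soft
    img = img * (1 - cup_soft) + np.asarray(_CUP_RGB, dtype=np.float32) * cup_soft

    _draw_vessels(img, params, rng)

    img += rng.normal(0.0, params.noise_sd, img.shape).astype(np.float32)
    np.clip(img, 0.0, 1.0, out=img)
    return FundusImage(pixels=img.astype(np.float32), disc_mask=disc_mask,
                       cup_mask=cup_mask, id=f"scene_{params.seed}")


# -- PNG / manifest I/O -------------------------------------------------------

def encode_mask_png(disc_mask: np.ndarray, cup_mask: np.ndarray) -> np.ndarray:
    out = np.zeros(disc_mask.shape, dtype=np.uint8)
    out[disc_mask] = 128
    out[cup_mask] = 255
    return out


def decode_mask_png(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    disc = arr >= 128
    cup = arr == 255
    return disc, cup


def _sample_params(rng: np.random.Generator, image_size: int) -> SceneParams:
    s = image_size
    a = rng.uniform(0.17, 0.24) * s
    b = rng.uniform(0.80, 1.00) * a
    center = (s / 2 + rng.uniform(-0.06, 0.06) * s, s / 2 + rng.uniform(-0.06, 0.06) * s)
    cup_scale = rng.uniform(0.30, 0.55)
    max_off = 0.3 * (1.0 - cup_scale) * b
    ang = rng.uniform(0, 2 * np.pi)
    rad = rng.uniform(0, max_off)
    return SceneParams(
        image_size=s,
        disc_center=(round(center[0], 2), round(center[1], 2)),
        disc_axes=(round(a, 2), round(b, 2)),
        disc_rotation=round(rng.uniform(0.0, 180.0), 2),
        cup_scale=round(float(cup_scale), 4),
        cup_offset=(round(rad * np.sin(ang), 2), round(rad * np.cos(ang), 2)),
        vessel_count=int(rng.integers(4, 9)),
        noise_sd=0.02,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def make_dataset(n: int, split: str, seed: int, out_dir, force: bool = False,
                 image_size: int = 128) -> dict:
    """Write ``n`` synthetic samples and a YAML manifest to ``out_dir``.

    ``split`` is one of ``train``, ``val``, ``unlabeled``; the unlabeled split
    omits mask files.  Refuses to overwrite an existing manifest unless
    ``force`` is given.  Deterministic: same arguments → byte-identical files.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if split not in ("train", "val", "unlabeled"):
        raise ValueError(f"unknown split {split!r}")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.yaml"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        params = None
        for _ in range(50):  # rejection loop; sampler bounds make this rarely repeat
            candidate = _sample_params(rng, image_size)
            try:
                _check_geometry(candidate)
            except InvalidGeometryError:
                continue
            params = candidate
            break
        if params is None:
            raise InvalidGeometryError("could not sample a valid scene")
        sid = f"{split}_{i:04d}"
        sample = make_sample(params)
        img_name = f"{sid}.png"
        iio.imwrite(out_dir / img_name,
                    np.round(sample.pixels * 255).astype(np.uint8))
        entry = {"id": sid, "image": img_name, "mask": None,
                 "params": params.to_dict()}
        if split != "unlabeled":
            mask_name = f"{sid}_mask.png"
            iio.imwrite(out_dir / mask_name,
                        encode_mask_png(sample.disc_mask, sample.cup_mask))
            entry["mask"] = mask_name
        samples.append(entry)

    manifest = {"split": split, "seed": int(seed), "image_size": int(image_size),
                "n": int(n), "samples": samples}
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def load_manifest(manifest_path) -> dict:
    manifest_path = Path(manifest_path)
    return yaml.safe_load(manifest_path.read_text())


def load_sample(manifest_path, entry: dict) -> FundusImage:
    """Read one manifest entry back into a :class:`FundusImage`."""
    base = Path(manifest_path).parent
    pixels = iio.imread(base / entry["image"]).astype(np.float32) / 255.0
    disc = cup = None
    if entry.get("mask"):
        disc, cup = decode_mask_png(iio.imread(base / entry["mask"]))
    return FundusImage(pixels=pixels, disc_mask=disc, cup_mask=cup, id=entry["id"])


def directory_digest(path) -> str:
    """SHA-256 over the sorted file names and contents of a dataset directory."""
    h = hashlib.sha256()
    for f in sorted(Path(path).iterdir()):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()
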