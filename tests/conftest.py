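"""Shared fixtures: synthetic datasets and a trained desk-scale checkpoint."""

from __future__ import annotations

import numpy as np
import pytest

from fundusseg.synthetic import make_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def train40_manifest(tmp_path_factory):
    """40 labeled training scenes (the desk-scale supervised corpus)."""
    d = tmp_path_factory.mktemp("train40")
    make_dataset(40, "train", seed=100, out_dir=d)
    return d / "manifest.yaml"


@pytest.fixture(scope="session")
def val10_manifest(tmp_path_factory):
    """10 held-out labeled scenes for evaluation."""
    d = tmp_path_factory.mktemp("val10")
    make_dataset(10, "val", seed=200, out_dir=d)
    return d / "manifest.yaml"


@pytest.fixture(scope="session")
def unlabeled16_manifest(tmp_path_factory):
    """16 unlabeled scenes for contrastive pretraining."""
    d = tmp_path_factory.mktemp("ul16")
    make_dataset(16, "unlabeled", seed=300, out_dir=d)
    return d / "manifest.yaml"


@pytest.fixture(scope="session")
def trained_checkpoint(tmp_path_factory, train40_manifest):
    """A 200-step desk-scale checkpoint shared by pipeline-level tests."""
    from fundusseg.model import ModelConfig
    from fundusseg.pipeline import TrainConfig, train

    path = tmp_path_factory.mktemp("ckpt") / "seg.npz"
    train(train40_manifest, path,
          TrainConfig(epochs=10, lr=3e-3, max_steps=200, seed=1),
          model_config=ModelConfig(seed=1),
          log_path=path.with_suffix(".csv"))
    return path


def finite_difference_grad(f, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        fp = f()
        flat[i] = orig - h
        fm = f()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * h)
    return g
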