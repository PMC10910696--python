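"""Training objectives.

``rim_loss`` is the rim-constrained multi-label segmentation loss: three
independent binary cross-entropies — disc vs. its ground truth, cup vs. its
ground truth, and the *rim* term which scores the probability difference
p_disc − p_cup against the rim ground truth g_disc − g_cup — averaged over
pixels and combined with equal weight 1/3.  The rim term injects the
anatomical prior that the cup lies inside the disc: the network is pushed to
keep p_disc ≥ p_cup wherever the rim is annotated.

Because the network may transiently predict p_cup > p_disc, the difference is
clamped to [eps, 1−eps] before the logarithm (the gradient passes through
only inside the clamp window).  The standard negative-log-likelihood sign
convention is used: the loss is non-negative and minimized at perfect
prediction.

``info_nce`` is the temperature-scaled contrastive objective

    L = −log exp(q·k₊/τ) / Σ_{i=0..K} exp(q·k_i/τ)

over one positive and K negative keys, i.e. a softmax cross-entropy with the
positive as the target class.  ``info_nce_batch`` applies it with in-batch
negatives over two augmented views of a mini-batch (K = 2·(batch−1)).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor, astensor

__all__ = ["rim_loss", "info_nce", "info_nce_batch"]


def _bce(p: Tensor, g: np.ndarray, eps: float) -> Tensor:
    p = nn.clip(p, eps, 1.0 - eps)
    g = np.asarray(g, dtype=np.float32)
    return -(g * nn.log(p) + (1.0 - g) * nn.log(1.0 - p)).mean()


def rim_loss(p_disc, p_cup, g_disc, g_cup, eps: float = 1e-6) -> Tensor:
    """Rim-constrained multi-label loss (Loss_D + Loss_C + Loss_R) / 3.

    Parameters are per-pixel disc/cup probabilities (tensors or arrays of any
    common shape) and binary ground-truth masks with g_cup ≤ g_disc
    everywhere; the rim ground truth is derived as g_disc − g_cup.
    """
    p_disc, p_cup = astensor(p_disc), astensor(p_cup)
    g_disc = np.asarray(g_disc, dtype=np.float32)
    g_cup = np.asarray(g_cup, dtype=np.float32)
    if np.any(g_cup > g_disc):
        raise ValueError("invalid ground truth: cup pixels outside the disc")
    g_rim = g_disc - g_cup
    loss_d = _bce(p_disc, g_disc, eps)
    loss_c = _bce(p_cup, g_cup, eps)
    loss_r = _bce(p_disc - p_cup, g_rim, eps)
    return (loss_d + loss_c + loss_r) * (1.0 / 3.0)


def info_nce(q, k_pos, k_neg, tau: float = 0.07) -> Tensor:
    """Contrastive loss for one query against one positive and K negatives.

    ``q`` and ``k_pos`` are unit-norm embeddings of shape (d,); ``k_neg`` is
    (K, d).  Finite for all inputs; raises on non-positive temperature.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    q, k_pos, k_neg = astensor(q), astensor(k_pos), astensor(k_neg)
    pos = (q * k_pos).sum().reshape(1)
    neg = (k_neg * q).sum(axis=1)                      # (K,)
    logits = nn.concat([pos, neg], axis=0) * (1.0 / tau)
    return -nn.log(nn.softmax(logits, axis=0)[0:1]).sum()


def info_nce_batch(z_a: Tensor, z_b: Tensor, tau: float = 0.07) -> Tensor:
    """In-batch InfoNCE over two views of a mini-batch.

    ``z_a`` and ``z_b`` are (B, d) unit-norm embeddings of paired views.
    Every embedding serves as a query once; its positive is its paired view
    and its negatives are the 2·(B−1) embeddings of all other images (its own
    other view is excluded from the denominator).  Returns the mean loss over
    the 2B queries.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    b = z_a.shape[0]
    z = nn.concat([z_a, z_b], axis=0)                  # (2B, d)
    sim = (z @ z.swapaxes(0, 1)) * (1.0 / tau)         # (2B, 2B)
    n = 2 * b
    pos_idx = np.concatenate([np.arange(b) + b, np.arange(b)])
    neg_mask = ~np.eye(n, dtype=bool)
    neg_mask[np.arange(n), pos_idx] = False            # negatives only
    # log-sum-exp over the positive plus the negatives (self excluded)
    keep = neg_mask.copy()
    keep[np.arange(n), pos_idx] = True
    shift = sim.data.max(axis=1, keepdims=True)
    exp_keep = nn.exp(sim - shift) * keep.astype(np.float32)
    log_denom = nn.log(exp_keep.sum(axis=1))
    pos_term = sim[np.arange(n), pos_idx] - shift[:, 0]
    return (log_denom - pos_term).mean()
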