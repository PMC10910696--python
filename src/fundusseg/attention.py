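"""Attention operators for the segmentation network.

Two bespoke blocks:

* **Multi-scale KNN attention** — a pre-norm multi-head self-attention
  residual step followed by a multi-scale MLP (MSMLP): each token gathers its
  k most similar tokens (cosine similarity of L2-normalized channel vectors,
  k ∈ {4, 6, 8}), passes the gathered neighborhood through two 1×1
  convolutions with a ReLU between, max-reduces over the neighbor axis and
  sums the per-scale results; both sub-steps are residual.

* **Aggregation attention** — tokens are clustered into C=3 groups
  (intended to separate cup / disc / background context) by a seeded
  mini-batch k-means; scaled dot-product attention runs separately inside
  each group and across the 3 cluster centroids, and each updated centroid is
  broadcast back and added to its members.

Token layout: a feature map of shape (B·N, C, h, w) is flattened to
(B, C, P) with P = N·h·w and position index p = n·h·w + r·w + c.

Neighbor selection and cluster assignment are discrete and carry no
gradient; gradients flow through the gathered values, the MLPs and the
attention projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, astensor

__all__ = [
    "TokenTensor",
    "NeighborIndex",
    "ClusterState",
    "DegenerateFeatureError",
    "flatten_tokens",
    "unflatten_tokens",
    "token_similarity",
    "topk_neighbors",
    "scaled_attention",
    "cluster_assign",
    "MultiHeadSelfAttention",
    "MSMLP",
    "MultiScaleAttention",
    "AggregationAttention",
]


class DegenerateFeatureError(ValueError):
    """A token's channel vector has zero norm; cosine similarity is undefined."""


@dataclass
class TokenTensor:
    """Flattened patch-token sequence with (batch, channels, positions) layout."""

    values: Tensor              # (B, C, P)
    grid_shape: tuple[int, int]  # (h, w) of the originating feature map
    group_size: int = 1          # N feature-map groups folded into the sequence

    def __post_init__(self):
        b, c, p = self.values.shape
        h, w = self.grid_shape
        if p != self.group_size * h * w:
            raise ValueError(
                f"positions {p} != group_size*h*w = {self.group_size}*{h}*{w}")

    @property
    def positions(self) -> int:
        return self.values.shape[2]

    @property
    def channels(self) -> int:
        return self.values.shape[1]


@dataclass
class NeighborIndex:
    indices: np.ndarray  # (B, P, k) int
    k: int


@dataclass
class ClusterState:
    labels: np.ndarray      # (P,) int in [0, n_clusters)
    centroids: np.ndarray   # (n_clusters, C)
    n_clusters: int


def flatten_tokens(feature_map: Tensor, n_groups: int = 1) -> TokenTensor:
    """(B·N, C, h, w) → (B, C, N·h·w) with p = n·h·w + r·w + c."""
    feature_map = astensor(feature_map)
    bn, c, h, w = feature_map.shape
    if bn % n_groups:
        raise ValueError(f"leading dimension {bn} not divisible by group size {n_groups}")
    b = bn // n_groups
    values = (feature_map.reshape(b, n_groups, c, h * w)
              .transpose(0, 2, 1, 3)
              .reshape(b, c, n_groups * h * w))
    return TokenTensor(values=values, grid_shape=(h, w), group_size=n_groups)


def unflatten_tokens(tokens: TokenTensor) -> Tensor:
    """Inverse of :func:`flatten_tokens`; exact round trip."""
    b, c, p = tokens.values.shape
    h, w = tokens.grid_shape
    n = tokens.group_size
    return (tokens.values.reshape(b, c, n, h * w)
            .transpose(0, 2, 1, 3)
            .reshape(b * n, c, h, w))


def _normalized_features(values: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise DegenerateFeatureError("zero-norm token channel vector")
    return values / norms


def token_similarity(x: TokenTensor) -> np.ndarray:
    """Pairwise cosine similarity S = FᵀF of L2-normalized channel vectors.

    The ℓ2 distance between unit vectors is monotone in their inner product,
    so nearest neighbors under ℓ2 equal top entries of S.  Returns a plain
    (B, P, P) array: neighbor selection is discrete and carries no gradient.
    """
    f = _normalized_features(x.values.data)
    return np.einsum("bcp,bcq->bpq", f, f)


def topk_neighbors(S: np.ndarray, k: int) -> NeighborIndex:
    """Per query row, the k highest-similarity positions (self included).

    Ties are broken toward the lower position index so results are
    reproducible across platforms.
    """
    b, p, q = S.shape
    if k > q:
        raise ValueError(f"k={k} exceeds the number of positions {q}")
    order = np.argsort(-S, axis=-1, kind="stable")
    return NeighborIndex(indices=order[:, :, :k].astype(np.int64), k=k)


def scaled_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """SoftMax(QKᵀ/√D)V over the second-to-last (sequence) axis."""
    q, k, v = astensor(q), astensor(k), astensor(v)
    d = q.shape[-1]
    attn = nn.softmax((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d)), axis=-1)
    return attn @ v


# -- mini-batch k-means -------------------------------------------------------

def _kmeans_pp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centers = np.empty((k, points.shape[1]), dtype=points.dtype)
    centers[0] = points[rng.integers(n)]
    d2 = ((points - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 1e-12:  # all points coincide with existing centers
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[j] = points[idx]
        d2 = np.minimum(d2, ((points - centers[j]) ** 2).sum(axis=1))
    return centers


def _assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d.argmin(axis=1)


def cluster_assign(x, n_clusters: int = 3, seed: int = 0, n_iter: int = 10,
                   batch_size: int = 256) -> ClusterState:
    """Seeded mini-batch k-means over L2-normalized token vectors.

    Accepts a :class:`TokenTensor` with B=1 or a (P, C) array.  Uses
    k-means++ initialization, ``n_iter`` mini-batch update rounds (Sculley
    per-center learning rates) and repairs empty clusters by re-seeding them
    at the point farthest from its assigned center.  Deterministic for a
    fixed seed.
    """
    if isinstance(x, TokenTensor):
        if x.values.shape[0] != 1:
            raise ValueError("cluster_assign expects a single batch item")
        points = _normalized_features(x.values.data)[0].T  # (P, C)
    else:
        points = np.asarray(x, dtype=np.float32)
    p = points.shape[0]
    if p < n_clusters:
        raise ValueError(f"need at least {n_clusters} tokens, got {p}")
    rng = np.random.default_rng(seed)
    centers = _kmeans_pp_init(points, n_clusters, rng)
    counts = np.zeros(n_clusters, dtype=np.int64)
    bs = min(batch_size, p)
    for _ in range(n_iter):
        batch = points[rng.choice(p, size=bs, replace=False)] if bs < p else points
        labels = _assign(batch, centers)
        for c in range(n_clusters):
            members = batch[labels == c]
            if len(members) == 0:
                continue
            counts[c] += len(members)
            eta = len(members) / counts[c]
            centers[c] = (1.0 - eta) * centers[c] + eta * members.mean(axis=0)
    labels = _assign(points, centers)
    # empty-cluster repair: re-seed at the farthest point from its center
    for _ in range(n_clusters):
        present = np.bincount(labels, minlength=n_clusters)
        empty = np.flatnonzero(present == 0)
        if empty.size == 0:
            break
        dist = ((points - centers[labels]) ** 2).sum(axis=1)
        centers[empty[0]] = points[dist.argmax()]
        labels = _assign(points, centers)
    return ClusterState(labels=labels, centroids=centers.copy(), n_clusters=n_clusters)


# -- modules ------------------------------------------------------------------

class MultiHeadSelfAttention(nn.Module):
    """MHSA over (B, C, P) tokens with learnable C×C projections.

    ``zero_init_out=True`` zeroes the output projection so the enclosing
    residual block starts as an exact identity.
    """

    def __init__(self, channels: int, heads: int, rng: np.random.Generator,
                 zero_init_out: bool = False):
        super().__init__()
        if channels % heads:
            raise ValueError(f"channels {channels} not divisible by heads {heads}")
        self.channels, self.heads = channels, heads
        self.head_dim = channels // heads
        self.w_q = nn.Linear(channels, channels, rng)
        self.w_k = nn.Linear(channels, channels, rng)
        self.w_v = nn.Linear(channels, channels, rng)
        self.w_o = nn.Linear(channels, channels, rng, zero_init=zero_init_out)

    def forward(self, values: Tensor) -> Tensor:
        b, c, p = values.shape
        h, d = self.heads, self.head_dim
        t = values.transpose(0, 2, 1)                       # (B, P, C)
        q = self.w_q(t).reshape(b, p, h, d).transpose(0, 2, 1, 3)
        k = self.w_k(t).reshape(b, p, h, d).transpose(0, 2, 1, 3)
        v = self.w_v(t).reshape(b, p, h, d).transpose(0, 2, 1, 3)
        o = scaled_attention(q, k, v)                        # (B, H, P, D)
        o = o.transpose(0, 2, 1, 3).reshape(b, p, c)
        return self.w_o(o).transpose(0, 2, 1)                # (B, C, P)


class MHSABlock(nn.Module):
    """Pre-norm residual attention step: MHSA(LN(X)) + X."""

    def __init__(self, channels: int, heads: int, rng: np.random.Generator,
                 zero_init_out: bool = False):
        super().__init__()
        self.norm = nn.LayerNorm(channels)
        self.attn = MultiHeadSelfAttention(channels, heads, rng, zero_init_out)

    def forward(self, tokens: TokenTensor) -> TokenTensor:
        out = self.attn(self.norm(tokens.values)) + tokens.values
        return TokenTensor(out, tokens.grid_shape, tokens.group_size)


def mhsa_block(x: TokenTensor, params: MHSABlock) -> TokenTensor:
    return params(x)


class MSMLP(nn.Module):
    """Multi-scale KNN neighborhood MLP.

    For each scale k the module gathers every token's k nearest neighbors
    (cosine similarity), applies φ — two 1×1 convolutions (channel-wise
    linear maps) with a ReLU between, shared across scales — max-reduces over
    the neighbor axis and sums the per-scale outputs.  ``zero_init_out=True``
    zeroes φ's second layer so the residual block starts as an identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 scales: tuple[int, ...] = (4, 6, 8), zero_init_out: bool = False):
        super().__init__()
        self.scales = tuple(scales)
        self.phi1 = nn.Linear(channels, channels, rng)
        self.phi2 = nn.Linear(channels, channels, rng, zero_init=zero_init_out)

    def forward(self, tokens: TokenTensor) -> TokenTensor:
        values = tokens.values
        b, c, p = values.shape
        if max(self.scales) > p:
            raise ValueError(f"largest scale {max(self.scales)} exceeds {p} tokens")
        sim = token_similarity(tokens)
        order = topk_neighbors(sim, max(self.scales)).indices   # one sort, all scales
        t = values.transpose(0, 2, 1)                            # (B, P, C)
        bidx = np.arange(b)[:, None, None]
        out = None
        for k in self.scales:
            gathered = t[bidx, order[:, :, :k], :]               # (B, P, k, C)
            h = nn.relu(self.phi1(gathered))
            piece = self.phi2(h).max(axis=2)                     # (B, P, C)
            out = piece if out is None else out + piece
        return TokenTensor(out.transpose(0, 2, 1), tokens.grid_shape, tokens.group_size)


def msmlp(x: TokenTensor, params: MSMLP) -> TokenTensor:
    return params(x)


class MultiScaleAttention(nn.Module):
    """Full multi-scale attention block:

        X' = MHSA(LN(X)) + X
        Y  = MSMLP(LN(X')) + X'
    """

    def __init__(self, channels: int, rng: np.random.Generator, heads: int = 4,
                 scales: tuple[int, ...] = (4, 6, 8), zero_init_out: bool = False):
        super().__init__()
        self.norm1 = nn.LayerNorm(channels)
        self.attn = MultiHeadSelfAttention(channels, heads, rng, zero_init_out)
        self.norm2 = nn.LayerNorm(channels)
        self.mlp = MSMLP(channels, rng, scales=scales, zero_init_out=zero_init_out)

    @property
    def config(self) -> dict:
        return {"heads": self.attn.heads, "scales": list(self.mlp.scales),
                "channels": self.attn.channels}

    def forward(self, tokens: TokenTensor) -> TokenTensor:
        x = tokens.values
        x1 = self.attn(self.norm1(x)) + x
        t1 = TokenTensor(x1, tokens.grid_shape, tokens.group_size)
        t1n = TokenTensor(self.norm2(x1), tokens.grid_shape, tokens.group_size)
        out = self.mlp(t1n).values + x1
        return TokenTensor(out, tokens.grid_shape, tokens.group_size)


def multi_scale_attention(x: TokenTensor, params: MultiScaleAttention) -> TokenTensor:
    return params(x)


class AggregationAttention(nn.Module):
    """Cluster-then-attend aggregation block.

    Tokens are grouped by seeded mini-batch k-means (intended: cup, disc,
    background).  Scaled dot-product attention with shared Q/K/V projections
    runs residually (i) inside each group over its member tokens and (ii)
    across the cluster centroids (the differentiable mean of each group's
    tokens) as a short sequence.  Each updated centroid is broadcast to its
    member positions and added to the updated member tokens.
    """

    def __init__(self, channels: int, rng: np.random.Generator, n_clusters: int = 3,
                 seed: int = 0, zero_init: bool = False):
        super().__init__()
        self.n_clusters = n_clusters
        self.seed = seed
        self.w_q = nn.Linear(channels, channels, rng, zero_init=zero_init)
        self.w_k = nn.Linear(channels, channels, rng, zero_init=zero_init)
        self.w_v = nn.Linear(channels, channels, rng, zero_init=zero_init)

    @property
    def config(self) -> dict:
        return {"n_clusters": self.n_clusters, "seed": self.seed}

    def _attend(self, x: Tensor) -> Tensor:
        """Residual single-head attention over a (P, C) sequence."""
        return x + scaled_attention(self.w_q(x), self.w_k(x), self.w_v(x))

    def forward(self, tokens: TokenTensor, labels: np.ndarray | None = None) -> TokenTensor:
        values = tokens.values
        b, c, p = values.shape
        outs = []
        for i in range(b):
            xi = values[i].transpose(1, 0)                  # (P, C)
            if labels is None:
                pts = _normalized_features(values.data[i:i + 1])[0].T
                state = cluster_assign(pts, self.n_clusters, seed=self.seed)
                lab = state.labels
            else:
                lab = labels
            member_updates, cents, owners = [], [], []
            for cidx in range(self.n_clusters):
                idx = np.flatnonzero(lab == cidx)
                if idx.size == 0:
                    continue
                xc = xi[idx]                                # (Pc, C)
                member_updates.append(self._attend(xc))
                cents.append(xc.mean(axis=0, keepdims=True))
                owners.append(idx)
            cent_seq = nn.concat(cents, axis=0)             # (G, C)
            cent_upd = self._attend(cent_seq)
            pieces = []
            for g, idx in enumerate(owners):
                pieces.append(member_updates[g] + cent_upd[g:g + 1])
            stacked = nn.concat(pieces, axis=0)             # (P, C) cluster-ordered
            inv = np.argsort(np.concatenate(owners), kind="stable")
            outs.append(stacked[inv].transpose(1, 0).reshape(1, c, p))
        out = outs[0] if b == 1 else nn.concat(outs, axis=0)
        return TokenTensor(out, tokens.grid_shape, tokens.group_size)


def aggregation_attention(x: TokenTensor, params: AggregationAttention,
                          labels: np.ndarray | None = None) -> TokenTensor:
    return params(x, labels=labels)
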