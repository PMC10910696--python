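"""Oracle equivalence, reductions and invariants of the attention operators.

Every bespoke operator is compared with an explicit-loop implementation on
random small instances; the residual blocks are checked to reduce to exact
closed forms under zero-initialized branch weights.
"""

import numpy as np
import pytest

from fundusseg import nn
from fundusseg.attention import (
    AggregationAttention,
    ClusterState,
    DegenerateFeatureError,
    MHSABlock,
    MSMLP,
    MultiHeadSelfAttention,
    MultiScaleAttention,
    TokenTensor,
    cluster_assign,
    flatten_tokens,
    scaled_attention,
    token_similarity,
    topk_neighbors,
    unflatten_tokens,
)
from fundusseg.nn import Tensor


def _tok(values: np.ndarray, h=None, w=None, n=1) -> TokenTensor:
    b, c, p = values.shape
    if h is None:
        h, w = 1, p // n
    return TokenTensor(Tensor(np.asarray(values, dtype=np.float32)), (h, w), n)


# -- flatten / unflatten ------------------------------------------------------

def test_flatten_round_trip(rng):
    x = Tensor(rng.normal(size=(2, 8, 3, 3)).astype(np.float32))
    tok = flatten_tokens(x)
    assert tok.positions == 9
    np.testing.assert_array_equal(unflatten_tokens(tok).data, x.data)


def test_flatten_group_ordering():
    # N=2 groups of h=w=1: position index = group index
    x = Tensor(np.arange(2 * 3).reshape(2, 3, 1, 1).astype(np.float32))
    tok = flatten_tokens(x, n_groups=2)
    assert tok.values.shape == (1, 3, 2)
    np.testing.assert_array_equal(tok.values.data[0, :, 0], x.data[0, :, 0, 0])
    np.testing.assert_array_equal(tok.values.data[0, :, 1], x.data[1, :, 0, 0])


def test_flatten_rejects_mismatched_group_size(rng):
    x = Tensor(rng.normal(size=(3, 4, 2, 2)).astype(np.float32))
    with pytest.raises(ValueError, match="group size"):
        flatten_tokens(x, n_groups=2)


# -- token similarity ---------------------------------------------------------

def test_similarity_identical_tokens_all_ones():
    v = np.ones((1, 4, 2), dtype=np.float32)
    np.testing.assert_allclose(token_similarity(_tok(v)), np.ones((1, 2, 2)),
                               atol=1e-6)


def test_similarity_orthonormal_tokens_identity():
    v = np.eye(4, dtype=np.float32)[None].transpose(0, 2, 1)  # 4 orthonormal tokens
    np.testing.assert_allclose(token_similarity(_tok(v)), np.eye(4)[None], atol=1e-6)


def test_similarity_matches_cosine_loop_oracle(rng):
    v = rng.normal(size=(1, 3, 5)).astype(np.float32)
    s = token_similarity(_tok(v))
    want = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            a, b = v[0, :, i], v[0, :, j]
            want[i, j] = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    np.testing.assert_allclose(s[0], want, atol=1e-5)
    np.testing.assert_allclose(s[0], s[0].T, atol=1e-6)
    assert np.linalg.eigvalsh(s[0]).min() > -1e-5  # Gram matrix is PSD


def test_similarity_rejects_zero_norm_token():
    v = np.zeros((1, 3, 2), dtype=np.float32)
    v[0, :, 0] = 1.0
    with pytest.raises(DegenerateFeatureError):
        token_similarity(_tok(v))


# -- top-k neighbors ----------------------------------------------------------

def test_topk_all_ties_resolved_by_index():
    s = np.ones((1, 3, 3))
    idx = topk_neighbors(s, 3).indices
    np.testing.assert_array_equal(idx[0], [[0, 1, 2]] * 3)


def test_topk_identity_selects_self():
    idx = topk_neighbors(np.eye(4)[None], 1).indices
    np.testing.assert_array_equal(idx[0, :, 0], np.arange(4))


def test_topk_matches_argsort_oracle(rng):
    for _ in range(100):
        s = rng.normal(size=(1, 6, 6))
        idx = topk_neighbors(s, 3).indices[0]
        want = np.argsort(-s[0], axis=1, kind="stable")[:, :3]
        np.testing.assert_array_equal(idx, want)


def test_topk_rejects_k_too_large():
    with pytest.raises(ValueError):
        topk_neighbors(np.eye(3)[None], 4)


# -- scaled attention ---------------------------------------------------------

def test_scaled_attention_singleton_returns_value(rng):
    q = Tensor(rng.normal(size=(1, 4)).astype(np.float32))
    k = Tensor(rng.normal(size=(1, 4)).astype(np.float32))
    v = Tensor(rng.normal(size=(1, 4)).astype(np.float32))
    np.testing.assert_allclose(scaled_attention(q, k, v).data, v.data, atol=1e-6)


def test_scaled_attention_identical_keys_average_values(rng):
    q = Tensor(rng.normal(size=(3, 4)).astype(np.float32))
    k = Tensor(np.tile(rng.normal(size=(1, 4)), (5, 1)).astype(np.float32))
    v = Tensor(rng.normal(size=(5, 4)).astype(np.float32))
    out = scaled_attention(q, k, v).data
    np.testing.assert_allclose(out, np.tile(v.data.mean(axis=0), (3, 1)), atol=1e-5)


def test_scaled_attention_matches_loop_oracle(rng):
    for _ in range(100):
        q, k, v = (rng.normal(size=(4, 4)).astype(np.float32) for _ in range(3))
        out = scaled_attention(Tensor(q), Tensor(k), Tensor(v)).data
        want = np.zeros((4, 4))
        for i in range(4):
            logits = np.array([q[i] @ k[j] / 2.0 for j in range(4)])  # sqrt(4)=2
            wts = np.exp(logits - logits.max())
            wts /= wts.sum()
            want[i] = sum(wts[j] * v[j] for j in range(4))
        np.testing.assert_allclose(out, want, atol=1e-5)


def test_scaled_attention_rows_sum_to_one(rng):
    q = Tensor(rng.normal(size=(5, 3)).astype(np.float32))
    k = Tensor(rng.normal(size=(5, 3)).astype(np.float32))
    attn = nn.softmax((q @ k.swapaxes(0, 1)) * (1 / np.sqrt(3)), axis=-1)
    np.testing.assert_allclose(attn.data.sum(axis=1), 1.0, atol=1e-6)


# -- MHSA ---------------------------------------------------------------------

def test_mhsa_zero_output_projection_is_identity(rng):
    blk = MHSABlock(8, heads=2, rng=rng, zero_init_out=True)
    tok = _tok(rng.normal(size=(1, 8, 6)).astype(np.float32))
    np.testing.assert_array_equal(blk(tok).values.data, tok.values.data)


def test_mhsa_single_token_is_value_path(rng):
    # softmax over one position is 1, so attention reduces to W_o(W_v x + b_v)
    attn = MultiHeadSelfAttention(4, heads=1, rng=rng)
    x = rng.normal(size=(1, 4, 1)).astype(np.float32)
    out = attn(Tensor(x)).data
    v = x[0, :, 0] @ attn.w_v.weight.data + attn.w_v.bias.data
    want = v @ attn.w_o.weight.data + attn.w_o.bias.data
    np.testing.assert_allclose(out[0, :, 0], want, atol=1e-5)


def test_mhsa_single_head_matches_loop_oracle(rng):
    attn = MultiHeadSelfAttention(4, heads=1, rng=rng)
    x = rng.normal(size=(1, 4, 5)).astype(np.float32)
    out = attn(Tensor(x)).data[0]
    t = x[0].T  # (P, C)
    q = t @ attn.w_q.weight.data + attn.w_q.bias.data
    k = t @ attn.w_k.weight.data + attn.w_k.bias.data
    v = t @ attn.w_v.weight.data + attn.w_v.bias.data
    want = np.zeros_like(t)
    for i in range(5):
        logits = np.array([q[i] @ k[j] for j in range(5)]) / 2.0
        w = np.exp(logits - logits.max())
        w /= w.sum()
        want[i] = sum(w[j] * v[j] for j in range(5))
    want = want @ attn.w_o.weight.data + attn.w_o.bias.data
    np.testing.assert_allclose(out.T, want, atol=1e-4)


# -- MSMLP --------------------------------------------------------------------

def _msmlp_oracle(mod: MSMLP, values: np.ndarray) -> np.ndarray:
    """Explicit gather/phi/max/sum loops."""
    b, c, p = values.shape
    f = values / np.linalg.norm(values, axis=1, keepdims=True)
    out = np.zeros_like(values)
    w1, b1 = mod.phi1.weight.data, mod.phi1.bias.data
    w2, b2 = mod.phi2.weight.data, mod.phi2.bias.data
    for bi in range(b):
        s = f[bi].T @ f[bi]
        order = np.argsort(-s, axis=1, kind="stable")
        for k in mod.scales:
            for pos in range(p):
                neigh = order[pos, :k]
                feats = []
                for j in neigh:
                    hid = np.maximum(values[bi, :, j] @ w1 + b1, 0.0)
                    feats.append(hid @ w2 + b2)
                out[bi, :, pos] += np.max(feats, axis=0)
    return out


def test_msmlp_matches_loop_oracle_on_random_instances(rng):
    for trial in range(100):
        c = int(rng.integers(2, 5))
        p = int(rng.integers(3, 9))
        scales = tuple(sorted(set(rng.integers(1, p + 1, size=2).tolist())))
        mod = MSMLP(c, rng, scales=scales)
        values = rng.normal(size=(1, c, p)).astype(np.float32) + 0.1
        out = mod(_tok(values)).values.data
        np.testing.assert_allclose(out, _msmlp_oracle(mod, values), atol=1e-5)


def test_msmlp_identity_phi_self_neighbor(rng):
    # phi = identity and k=1 with orthonormal tokens: each token sees itself
    c = 4
    mod = MSMLP(c, rng, scales=(1,))
    mod.phi1.weight.data = np.eye(c, dtype=np.float32)
    mod.phi1.bias.data[:] = 0
    mod.phi2.weight.data = np.eye(c, dtype=np.float32)
    mod.phi2.bias.data[:] = 0
    values = np.eye(c, dtype=np.float32)[None].transpose(0, 2, 1) + 0.0
    values += 0.2  # strictly positive so the ReLU is inactive
    out = mod(_tok(values)).values.data
    np.testing.assert_allclose(out, values, atol=1e-6)


def test_msmlp_constant_field_gives_constant_output(rng):
    mod = MSMLP(3, rng, scales=(2, 3))
    values = np.tile(np.array([0.5, -1.0, 2.0], dtype=np.float32)[None, :, None],
                     (1, 1, 6))
    out = mod(_tok(values)).values.data
    np.testing.assert_allclose(out, np.tile(out[:, :, :1], (1, 1, 6)), atol=1e-6)


def test_msmlp_rejects_scale_larger_than_tokens(rng):
    mod = MSMLP(3, rng, scales=(4, 6, 8))
    with pytest.raises(ValueError, match="scale"):
        mod(_tok(rng.normal(size=(1, 3, 4)).astype(np.float32)))


# -- full multi-scale block ---------------------------------------------------

def test_multi_scale_block_zero_init_is_identity(rng):
    blk = MultiScaleAttention(8, rng, heads=2, scales=(2, 3), zero_init_out=True)
    tok = _tok(rng.normal(size=(2, 8, 6)).astype(np.float32))
    np.testing.assert_array_equal(blk(tok).values.data, tok.values.data)


@pytest.mark.parametrize("h,w,n", [(2, 3, 1), (1, 8, 1), (2, 2, 2)])
def test_multi_scale_block_preserves_shape(h, w, n, rng):
    blk = MultiScaleAttention(4, rng, heads=2, scales=(2, 4))
    tok = _tok(rng.normal(size=(1, 4, n * h * w)).astype(np.float32), h=h, w=w, n=n)
    out = blk(tok)
    assert out.values.shape == tok.values.shape
    assert out.grid_shape == (h, w) and out.group_size == n


def test_multi_scale_block_gradient_reaches_all_parameters(rng):
    blk = MultiScaleAttention(4, rng, heads=2, scales=(2,))
    tok = _tok(rng.normal(size=(1, 4, 5)).astype(np.float32))
    out = blk(tok)
    (out.values * out.values).sum().backward()
    for name, p in blk.named_parameters():
        assert p.grad is not None, f"no gradient for {name}"
    # finite-difference spot check on one attention weight
    w = blk.attn.w_q.weight

    def f():
        o = blk(_tok(tok.values.data)).values.data
        return float((o * o).sum())

    i, j = 1, 2
    h = 1e-2
    orig = w.data[i, j]
    w.data[i, j] = orig + h
    fp = f()
    w.data[i, j] = orig - h
    fm = f()
    w.data[i, j] = orig
    np.testing.assert_allclose(w.grad[i, j], (fp - fm) / (2 * h), rtol=0.05,
                               atol=1e-3)


# -- clustering ---------------------------------------------------------------

def test_kmeans_recovers_separated_groups(rng):
    centers = np.array([[10, 0], [-10, 0], [0, 10]], dtype=np.float32)
    pts = np.concatenate([c + rng.normal(0, 0.1, (5, 2)).astype(np.float32)
                          for c in centers])
    state = cluster_assign(pts, 3, seed=0)
    labels = state.labels.reshape(3, 5)
    # each true triplet maps to exactly one predicted cluster
    assert all(len(set(row)) == 1 for row in labels.tolist())
    assert len({row[0] for row in labels.tolist()}) == 3


def test_kmeans_matches_sklearn_partition_on_blobs(rng):
    sklearn = pytest.importorskip("sklearn")
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    centers = np.array([[5, 5], [-5, 5], [0, -6]], dtype=np.float32)
    pts = np.concatenate([c + rng.normal(0, 0.2, (8, 2)).astype(np.float32)
                          for c in centers])
    ours = cluster_assign(pts, 3, seed=1).labels
    ref = KMeans(3, n_init=5, random_state=0).fit_predict(pts)
    assert adjusted_rand_score(ours, ref) == 1.0


def test_kmeans_identical_tokens_terminates():
    pts = np.ones((6, 3), dtype=np.float32)
    state = cluster_assign(pts, 3, seed=0)
    assert len(set(state.labels.tolist())) == 1


def test_kmeans_deterministic(rng):
    pts = rng.normal(size=(20, 4)).astype(np.float32)
    a = cluster_assign(pts, 3, seed=5)
    b = cluster_assign(pts, 3, seed=5)
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_array_equal(a.centroids, b.centroids)


def test_kmeans_rejects_too_few_tokens():
    with pytest.raises(ValueError):
        cluster_assign(np.ones((2, 3), dtype=np.float32), 3, seed=0)


# -- aggregation attention ----------------------------------------------------

def test_aggregation_zero_init_adds_centroid(rng):
    blk = AggregationAttention(4, rng, n_clusters=1, zero_init=True)
    values = rng.normal(size=(1, 4, 6)).astype(np.float32)
    out = blk(_tok(values)).values.data
    centroid = values[0].mean(axis=1, keepdims=True)
    np.testing.assert_allclose(out, values + centroid[None], atol=1e-5)


@pytest.mark.parametrize("p", [5, 9, 16])
def test_aggregation_shape_contract(p, rng):
    blk = AggregationAttention(4, rng, n_clusters=3, seed=0)
    tok = _tok(rng.normal(size=(1, 4, p)).astype(np.float32))
    assert blk(tok).values.shape == (1, 4, p)


def test_aggregation_permutation_equivariant_with_fixed_labels(rng):
    blk = AggregationAttention(4, rng, n_clusters=2, seed=0)
    values = rng.normal(size=(1, 4, 8)).astype(np.float32)
    labels = np.array([0, 1, 0, 1, 1, 0, 0, 1])
    out = blk(_tok(values), labels=labels).values.data
    perm = rng.permutation(8)
    out_p = blk(_tok(values[:, :, perm]), labels=labels[perm]).values.data
    np.testing.assert_allclose(out_p[:, :, np.argsort(perm)], out, atol=1e-5)
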