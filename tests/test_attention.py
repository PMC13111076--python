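"""Dual-path attention against quadratic-order and loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtsnet import nn
from rtsnet.attention import (AttentionConfig, DualPathAttention,
                              channel_attention, dual_path_forward,
                              efficient_attention)
from rtsnet.errors import ConfigurationError, ShapeError


def softmax_np(x, axis):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def quadratic_order_oracle(Q, K, V):
    """(rho_q(Q) rho_k(K)^T) V — the n×n association order."""
    return (softmax_np(Q, -1) @ softmax_np(K, -2).T) @ V


def channel_loop_oracle(Q, K, V, r):
    """Naive triple-loop evaluation of V softmax(K^T Q / r)."""
    n, d = Q.shape
    cov = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            cov[i, j] = sum(K[p, i] * Q[p, j] for p in range(n)) / r
    att = np.zeros((d, d))
    for j in range(d):
        col = np.exp(cov[:, j] - cov[:, j].max())
        att[:, j] = col / col.sum()
    out = np.zeros((n, d))
    for p in range(n):
        for j in range(d):
            out[p, j] = sum(V[p, i] * att[i, j] for i in range(d))
    return out


# --------------------------------------------------------------------------
# efficient attention
# --------------------------------------------------------------------------

def test_single_position_collapses_to_value():
    rng = np.random.default_rng(0)
    Q, K, V = rng.normal(size=(3, 1, 5)), rng.normal(size=(1, 5)), \
        rng.normal(size=(1, 4))
    out = efficient_attention(Q[0], K, V).data
    assert np.allclose(out, V, atol=1e-12)


def test_zero_values_give_zero_output():
    rng = np.random.default_rng(1)
    out = efficient_attention(rng.normal(size=(6, 3)),
                              rng.normal(size=(6, 3)), np.zeros((6, 4))).data
    assert np.allclose(out, 0.0)


def test_matches_quadratic_order_oracle():
    rng = np.random.default_rng(2)
    Q = rng.normal(size=(7, 4))
    K = rng.normal(size=(7, 4))
    V = rng.normal(size=(7, 4))
    out = efficient_attention(Q, K, V).data
    assert np.abs(out - quadratic_order_oracle(Q, K, V)).max() < 1e-5


@given(st.integers(1, 64), st.integers(1, 32), st.integers(0, 10_000))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_association_orders_agree_for_random_shapes(n, d, seed):
    rng = np.random.default_rng(seed)
    Q, K, V = (rng.normal(size=(n, d)) for _ in range(3))
    out = efficient_attention(Q, K, V).data
    assert np.abs(out - quadratic_order_oracle(Q, K, V)).max() < 1e-5


def test_permutation_equivariance_in_queries():
    rng = np.random.default_rng(3)
    Q, K, V = (rng.normal(size=(9, 5)) for _ in range(3))
    perm = rng.permutation(9)
    a = efficient_attention(Q[perm], K, V).data
    b = efficient_attention(Q, K, V).data[perm]
    assert np.allclose(a, b, atol=1e-12)


def test_shape_mismatch_raises():
    with pytest.raises(ShapeError):
        efficient_attention(np.zeros((3, 4)), np.zeros((3, 5)), np.zeros((3, 4)))
    with pytest.raises(ShapeError):
        efficient_attention(np.zeros((3, 4)), np.zeros((5, 4)), np.zeros((3, 4)))


# --------------------------------------------------------------------------
# channel attention
# --------------------------------------------------------------------------

def test_single_channel_collapses_to_value():
    rng = np.random.default_rng(4)
    Q, K, V = (rng.normal(size=(5, 1)) for _ in range(3))
    assert np.allclose(channel_attention(Q, K, V, 1.0).data, V, atol=1e-12)


def test_zero_keys_give_channelwise_mean():
    rng = np.random.default_rng(5)
    Q = rng.normal(size=(6, 3))
    V = rng.normal(size=(6, 3))
    out = channel_attention(Q, np.zeros((6, 3)), V, 2.0).data
    expected = np.repeat(V.mean(axis=1, keepdims=True), 3, axis=1)
    assert np.allclose(out, expected, atol=1e-12)


def test_matches_triple_loop_oracle():
    rng = np.random.default_rng(6)
    Q, K, V = (rng.normal(size=(6, 3)) for _ in range(3))
    out = channel_attention(Q, K, V, 1.7).data
    assert np.abs(out - channel_loop_oracle(Q, K, V, 1.7)).max() < 1e-6


def test_attention_matrix_is_column_stochastic():
    rng = np.random.default_rng(7)
    Q, K = rng.normal(size=(11, 6)), rng.normal(size=(11, 6))
    att = nn.softmax(nn.Tensor(K.T @ Q / 1.3), axis=-2).data
    assert np.abs(att.sum(axis=0) - 1.0).max() < 1e-6


def test_large_temperature_approaches_uniform_mixing():
    rng = np.random.default_rng(8)
    Q, K, V = (rng.normal(size=(8, 4)) for _ in range(3))
    out = channel_attention(Q, K, V, 1e6).data
    uniform = np.repeat(V.mean(axis=1, keepdims=True), 4, axis=1)
    assert np.abs(out - uniform).max() < 1e-4


# --------------------------------------------------------------------------
# dual-path block
# --------------------------------------------------------------------------

def _zero_weights(block):
    for p in block.parameters():
        if p is not block.r:
            p.data = np.zeros_like(p.data)


def test_block_preserves_shape_and_validates_channels():
    nn.seed_all(0)
    block = DualPathAttention(AttentionConfig(channels=8, heads=2))
    x = nn.Tensor(np.random.default_rng(0).normal(size=(2, 8, 5, 7))
                  .astype(np.float32))
    assert block(x).shape == (2, 8, 5, 7)
    with pytest.raises(ShapeError):
        block(nn.Tensor(np.zeros((1, 4, 5, 7), np.float32)))


def test_zero_projections_make_identity():
    nn.seed_all(1)
    block = DualPathAttention(AttentionConfig(channels=6, heads=1))
    _zero_weights(block)
    x = np.random.default_rng(1).normal(size=(1, 6, 4, 4)).astype(np.float32)
    assert np.allclose(block(nn.Tensor(x)).data, x, atol=1e-7)


def test_multi_head_split_matches_per_head_loop():
    nn.seed_all(2)
    heads, C = 3, 12
    block = DualPathAttention(AttentionConfig(channels=C, heads=heads))
    rng = np.random.default_rng(2)
    x = rng.normal(size=(1, C, 3, 4)).astype(np.float64)
    out = block(nn.Tensor(x)).data

    def conv1x1(m, v):
        w = m.weight.data.reshape(m.weight.data.shape[0], C)
        return np.einsum("oc,cn->on", w, v) + m.bias.data[:, None]

    tok = x[0].reshape(C, -1)                       # C, n
    dh = C // heads
    # spatial path, head by head
    q = conv1x1(block.spatial.q, tok)
    k = conv1x1(block.spatial.k, tok)
    v = conv1x1(block.spatial.v, tok)
    eff = np.zeros_like(tok)
    for h in range(heads):
        s = slice(h * dh, (h + 1) * dh)
        eff[s] = quadratic_order_oracle(q[s].T, k[s].T, v[s].T).T
    y = tok + conv1x1(block.spatial.proj, eff)
    # channel path, head by head
    q = conv1x1(block.channel.q, y)
    k = conv1x1(block.channel.k, y)
    v = conv1x1(block.channel.v, y)
    ch = np.zeros_like(tok)
    for h in range(heads):
        s = slice(h * dh, (h + 1) * dh)
        qh = q[s].T / np.sqrt((q[s].T ** 2).sum(0, keepdims=True) + 1e-6)
        kh = k[s].T / np.sqrt((k[s].T ** 2).sum(0, keepdims=True) + 1e-6)
        ch[s] = channel_loop_oracle(qh, kh, v[s].T,
                                    float(block.r.data[h])).T
    ref = (y + conv1x1(block.channel.proj, ch)).reshape(1, C, 3, 4)
    assert np.abs(out - ref).max() < 1e-4


def test_degenerate_projections_make_heads_irrelevant():
    # zero Q/K make the spatial path a uniform mix (independent of the head
    # split); a zeroed channel-path output projection removes the only other
    # head-dependent term, so every head count must agree
    rng = np.random.default_rng(3)
    x = rng.normal(size=(1, 8, 3, 3)).astype(np.float32)
    outs = []
    for heads in (1, 2, 4):
        nn.seed_all(9)
        block = DualPathAttention(AttentionConfig(channels=8, heads=heads))
        for m in (block.spatial.q, block.spatial.k, block.channel.proj):
            m.weight.data = np.zeros_like(m.weight.data)
            m.bias.data = np.zeros_like(m.bias.data)
        outs.append(block(nn.Tensor(x)).data)
    assert np.allclose(outs[0], outs[1], atol=1e-5)
    assert np.allclose(outs[0], outs[2], atol=1e-5)


def test_heads_must_divide_channels():
    with pytest.raises(ConfigurationError):
        AttentionConfig(channels=10, heads=4)


def test_functional_entry_builds_from_config():
    nn.seed_all(4)
    out = dual_path_forward(np.zeros((1, 4, 2, 2), np.float32),
                            AttentionConfig(channels=4, heads=1))
    assert out.shape == (1, 4, 2, 2)
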