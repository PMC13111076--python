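"""Serial dual-path attention: efficient (spatial) then channel attention.

The spatial path uses softmax-factorised attention,

    E(Q, K, V) = rho_q(Q) · (rho_k(K)^T V),

with ``rho_q`` a softmax over the key dimension per query position and
``rho_k`` a softmax over positions per key dimension.  Association order
makes the cost linear in the number of positions: the dk × dv context
matrix is formed first.

The channel path attends over the d × d channel covariance instead of the
n × n position matrix,

    C(Q, K, V) = V · softmax(K^T Q / r),

with the softmax normalising each column and ``r`` a learnable per-head
temperature regulating the smoothness of the distribution (r -> inf gives
uniform channel mixing).

Both paths project Q/K/V with their own 1×1 convolutions, run multi-head,
and are wrapped in residual additions with a per-path output projection,
so that the block is an identity map at zero projection weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError


@dataclass(frozen=True)
class AttentionConfig:
    channels: int
    heads: int | None = None        # default: channels // 64, at least 1
    r_init: float = 1.0

    def resolved_heads(self) -> int:
        h = self.heads if self.heads is not None else max(1, self.channels // 64)
        if self.channels % h != 0:
            raise ConfigurationError(
                f"heads ({h}) must divide channels ({self.channels})")
        return h

    def __post_init__(self):
        if self.r_init <= 0:
            raise ConfigurationError("r_init must be positive")
        self.resolved_heads()


def _as_tensor(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x))


def efficient_attention(Q, K, V) -> nn.Tensor:
    """Linear-order softmax-factorised attention on (..., n, d) matrices.

    ``Q`` is (..., n_q, dk); ``K`` (..., n, dk); ``V`` (..., n, dv).
    The dk × dv context matrix is contracted first.
    """
    Q, K, V = _as_tensor(Q), _as_tensor(K), _as_tensor(V)
    if Q.shape[-1] != K.shape[-1]:
        raise ShapeError(f"Q/K key dims differ: {Q.shape[-1]} vs {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ShapeError(f"K/V position counts differ: {K.shape[-2]} vs "
                         f"{V.shape[-2]}")
    qn = nn.softmax(Q, axis=-1)                       # per position, over keys
    kn = nn.softmax(K, axis=-2)                       # per key dim, over positions
    context = kn.transpose(*range(kn.ndim - 2), kn.ndim - 1, kn.ndim - 2) @ V
    return qn @ context


def channel_attention(Q, K, V, r) -> nn.Tensor:
    """Channel-transpose attention ``V @ softmax(K^T Q / r)`` on (..., n, d)
    matrices; the softmax normalises each column of the d × d map."""
    Q, K, V = _as_tensor(Q), _as_tensor(K), _as_tensor(V)
    if not (Q.shape == K.shape == V.shape):
        raise ShapeError(f"channel_attention expects equal shapes, got "
                         f"{Q.shape}, {K.shape}, {V.shape}")
    r = r if isinstance(r, nn.Tensor) else nn.Tensor(np.asarray(r))
    kt = K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2)
    att = nn.softmax((kt @ Q) / r, axis=-2)           # columns sum to 1
    return V @ att


class _PathProjections(nn.Module):
    """Per-path 1×1-convolution Q/K/V generators plus output projection."""

    def __init__(self, channels: int):
        super().__init__()
        self.q = nn.Conv2d(channels, channels, 1, bias=True)
        self.k = nn.Conv2d(channels, channels, 1, bias=True)
        self.v = nn.Conv2d(channels, channels, 1, bias=True)
        self.proj = nn.Conv2d(channels, channels, 1, bias=True)


def _l2_normalize(x: nn.Tensor, eps: float = 1e-6) -> nn.Tensor:
    """Unit-normalise along the position axis of a (..., n, d) matrix."""
    return x / nn.sqrt((x * x).sum(axis=-2, keepdims=True) + eps)


def _split_heads(x: nn.Tensor, heads: int) -> nn.Tensor:
    """(B, C, H, W) -> (B, heads, H·W, C/heads) token view."""
    B, C, H, W = x.shape
    t = x.reshape(B, heads, C // heads, H * W)
    return t.transpose(0, 1, 3, 2)


def _merge_heads(t: nn.Tensor, shape) -> nn.Tensor:
    B, C, H, W = shape
    return t.transpose(0, 1, 3, 2).reshape(B, C, H, W)


class DualPathAttention(nn.Module):
    """Serial efficient-attention -> channel-attention block on feature maps.

    Output = x + P1(EffAttn(x)) followed by y + P2(ChanAttn(y)); shape is
    preserved exactly.
    """

    def __init__(self, config: AttentionConfig):
        super().__init__()
        self.config = config
        self.heads = config.resolved_heads()
        self.spatial = _PathProjections(config.channels)
        self.channel = _PathProjections(config.channels)
        self.r = nn.Parameter(np.full(self.heads, config.r_init,
                                      dtype=np.float32))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.config.channels:
            raise ShapeError(f"expected {self.config.channels} channels, "
                             f"got {x.shape[1]}")
        h = self.heads
        shape = x.shape

        p = self.spatial
        e = efficient_attention(_split_heads(p.q(x), h),
                                _split_heads(p.k(x), h),
                                _split_heads(p.v(x), h))
        y = x + p.proj(_merge_heads(e, shape))

        p = self.channel
        r = self.r.reshape(1, h, 1, 1)
        # L2-normalise each channel's token vector before the covariance
        # (the channel-transpose-attention convention; keeps K^T Q bounded
        # so the temperature r alone controls the distribution's sharpness)
        c = channel_attention(_l2_normalize(_split_heads(p.q(y), h)),
                              _l2_normalize(_split_heads(p.k(y), h)),
                              _split_heads(p.v(y), h), r)
        return y + p.proj(_merge_heads(c, shape))


def dual_path_forward(x, block: DualPathAttention | AttentionConfig) -> nn.Tensor:
    """Functional entry point; accepts a configured block or builds a fresh
    randomly initialised one from a config."""
    if isinstance(block, AttentionConfig):
        block = DualPathAttention(block)
    return block(_as_tensor(x))
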