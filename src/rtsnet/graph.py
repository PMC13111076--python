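"""KNN-graph dynamic convolution block for decoder feature maps.

Feature pixels are treated as graph nodes; adjacency is rebuilt on every
forward pass from current feature distances (a dynamic graph, not image
topology), after the vision-GNN family of models.  The block is

    GCB(x) = R(BN(C(GConv(R(BN(C(x)))))))          (residual optional)
    GConv(x) = GELU(BN(DynConv(x)))

where C is a 1×1 convolution, BN batch normalisation, R the ReLU, and
DynConv a neighbourhood aggregation over the k-nearest-neighbour graph.
The default aggregation is max-relative convolution,

    m_i = max_{j in N(i)} (x_j - x_i),    out_i = W [x_i ‖ m_i],

with edge convolution, GraphSAGE and GIN available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError

CONV_VARIANTS = ("max_relative", "edge", "sage", "gin")


@dataclass(frozen=True)
class GCBConfig:
    channels: int
    k: int = 9
    conv_variant: str = "max_relative"
    dilation: int = 1
    hidden_ratio: float = 1.75     # width of the inner GConv relative to channels
    residual: bool = True

    def __post_init__(self):
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.dilation < 1:
            raise ConfigurationError("dilation must be >= 1")
        if self.conv_variant not in CONV_VARIANTS:
            raise ConfigurationError(
                f"unknown conv_variant {self.conv_variant!r}; "
                f"expected one of {CONV_VARIANTS}")

    @property
    def hidden(self) -> int:
        return max(1, int(round(self.channels * self.hidden_ratio)))


def knn_graph(x: np.ndarray, k: int, dilation: int = 1) -> np.ndarray:
    """Per-node k-nearest-neighbour index table in feature space.

    ``x`` is (N, D) or batched (B, N, D); returns (N, k) or (B, N, k).
    Distances are squared Euclidean; self-loops are excluded; ties break
    toward the lower node index.  With dilation d > 1 every d-th neighbour
    among the k·d nearest is kept.  If fewer than k neighbours exist, rows
    are padded by repeating the last valid neighbour.
    """
    x = x.data if isinstance(x, nn.Tensor) else np.asarray(x)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    B, n, _ = x.shape
    if n < 2:
        raise ValueError("knn_graph needs at least 2 nodes")
    sq = (x * x).sum(-1)
    d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * np.einsum(
        "bnd,bmd->bnm", x, x, optimize=True)
    bi = np.arange(n)
    d2[:, bi, bi] = np.inf
    order = np.argsort(d2, axis=-1, kind="stable")    # stable => low-index ties
    take = min(k * dilation, n - 1)
    nbrs = order[:, :, :take][:, :, ::dilation]
    if nbrs.shape[-1] < k:                            # pad with last valid
        pad = np.repeat(nbrs[:, :, -1:], k - nbrs.shape[-1], axis=-1)
        nbrs = np.concatenate([nbrs, pad], axis=-1)
    else:
        nbrs = nbrs[:, :, :k]
    return nbrs[0] if squeeze else nbrs


def max_relative_conv(x, g: np.ndarray, weights: nn.Linear) -> nn.Tensor:
    """Max-relative aggregation followed by the 2d -> d linear map.

    ``x`` is (B, N, D) (a plain array is wrapped), ``g`` the (B, N, K)
    neighbour table, ``weights`` a Linear(2D, D).
    """
    x = x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x))
    if g.ndim == 2:
        g = g[None]
    if g.shape[:2] != x.shape[:2]:
        raise ShapeError(f"graph table {g.shape} does not match nodes "
                         f"{x.shape}")
    nb = nn.gather_nodes(x, g)                        # B, N, K, D
    m = (nb - x.reshape(x.shape[0], x.shape[1], 1, x.shape[2])).max(axis=2)
    return weights(nn.cat([x, m], axis=-1))


class GConv(nn.Module):
    """DynConv -> BN -> GELU on flattened node features (B, N, D)."""

    def __init__(self, config: GCBConfig, dim: int | None = None):
        super().__init__()
        self.config = config
        d = dim if dim is not None else config.channels
        self.dim = d
        v = config.conv_variant
        if v in ("max_relative", "edge", "sage"):
            self.lin = nn.Linear(2 * d, d)
        elif v == "gin":
            self.lin = nn.Linear(d, d)
            self.eps = nn.Parameter(np.zeros(1, dtype=np.float32))
        self.bn = nn.BatchNormNodes(d)

    def aggregate(self, x: nn.Tensor, g: np.ndarray) -> nn.Tensor:
        B, N, D = x.shape
        v = self.config.conv_variant
        if v == "max_relative":
            return max_relative_conv(x, g, self.lin)
        nb = nn.gather_nodes(x, g)                    # B, N, K, D
        xc = x.reshape(B, N, 1, D)
        if v == "edge":
            # max_j W[x_i ‖ x_j - x_i] per edge
            K = g.shape[-1]
            centre = nn.cat([xc] * K, axis=2) if K > 1 else xc
            feats = nn.cat([centre, nb - xc], axis=-1)
            return self.lin(feats).max(axis=2)
        if v == "sage":
            return self.lin(nn.cat([x, nb.mean(axis=2)], axis=-1))
        # gin: W((1 + eps) x_i + sum_j x_j)
        return self.lin(x * (1.0 + self.eps) + nb.sum(axis=2))

    def forward(self, x) -> nn.Tensor:
        x = x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x))
        g = knn_graph(x.data, self.config.k, self.config.dilation)
        return nn.gelu(self.bn(self.aggregate(x, g)))


def gconv(x, config: GCBConfig, module: GConv | None = None) -> nn.Tensor:
    """Functional GConv; builds a fresh module unless one is supplied."""
    m = module if module is not None else GConv(config)
    return m(x)


class GraphConvBlock(nn.Module):
    """Full GCB: 1×1 conv -> BN -> ReLU -> GConv -> 1×1 conv -> BN -> ReLU
    on the flattened node view of a (B, C, H, W) map, with an optional
    residual connection around the whole block."""

    def __init__(self, config: GCBConfig):
        super().__init__()
        self.config = config
        C, Ch = config.channels, config.hidden
        self.conv_in = nn.Conv2d(C, Ch, 1, bias=True)
        self.bn_in = nn.BatchNorm2d(Ch)
        self.gconv = GConv(config, dim=Ch)
        self.conv_out = nn.Conv2d(Ch, C, 1, bias=True)
        self.bn_out = nn.BatchNorm2d(C)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.config.channels:
            raise ShapeError(f"expected {self.config.channels} channels, "
                             f"got {x.shape[1]}")
        B, C, H, W = x.shape
        h = nn.relu(self.bn_in(self.conv_in(x)))
        nodes = h.reshape(B, self.config.hidden, H * W).transpose(0, 2, 1)
        nodes = self.gconv(nodes)
        h = nodes.transpose(0, 2, 1).reshape(B, self.config.hidden, H, W)
        h = nn.relu(self.bn_out(self.conv_out(h)))
        return x + h if self.config.residual else h


def gcb_forward(x, block: GraphConvBlock | GCBConfig) -> nn.Tensor:
    if isinstance(block, GCBConfig):
        block = GraphConvBlock(block)
    return block(x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x)))
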