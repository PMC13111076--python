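"""Four-stage hierarchical transformer encoder (PVT-v2-b2 design).

Overlapping patch embeddings downsample by 4, 2, 2, 2 so the encoder emits
a feature pyramid at strides (4, 8, 16, 32) with channels (64, 128, 320,
512).  Each stage stacks transformer blocks with spatial-reduction
attention (key/value maps pooled by a strided convolution, ratios
8/4/2/1) and convolutional MLPs (a 3×3 depthwise convolution between the
two linear layers).  Stage depths are (3, 4, 6, 3), heads (1, 2, 5, 8),
MLP expansion (8, 8, 4, 4).

The published model initialises this encoder from ImageNet pretraining as
a soft anatomical prior; here weights are randomly initialised
(truncated-normal projections, zero biases) and an optional name-matched
import hook accepts externally supplied pretrained weights.  Every
structural property of the pyramid holds at random init.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError

BASE_CHANNELS = (64, 128, 320, 512)
DEPTHS = (3, 4, 6, 3)
HEADS = (1, 2, 5, 8)
SR_RATIOS = (8, 4, 2, 1)
MLP_RATIOS = (8, 8, 4, 4)
STRIDES = (4, 8, 16, 32)


@dataclass(frozen=True)
class EncoderConfig:
    variant: str = "b2"
    width_multiplier: float = 1.0
    drop_path_rate: float = 0.1

    def __post_init__(self):
        if self.variant not in ("b2", "tiny"):
            raise ConfigurationError(f"unknown encoder variant "
                                     f"{self.variant!r}; expected b2 or tiny")
        if self.variant == "b2" and self.width_multiplier != 1.0:
            raise ConfigurationError("width_multiplier must be 1 for b2")
        if not (0.0 < self.width_multiplier <= 1.0):
            raise ConfigurationError("width_multiplier must lie in (0, 1]")
        if not (0.0 <= self.drop_path_rate < 1.0):
            raise ConfigurationError("drop_path_rate must lie in [0, 1)")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(int(c * self.width_multiplier) for c in BASE_CHANNELS)


@dataclass
class FeaturePyramid:
    """Ordered multi-scale encoder outputs, shallow (stride 4) to deep
    (stride 32)."""
    stages: list[nn.Tensor]

    def __post_init__(self):
        if len(self.stages) != 4:
            raise ShapeError("a feature pyramid has exactly 4 stages")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(s.shape[1] for s in self.stages)

    @property
    def strides(self) -> tuple[int, ...]:
        return STRIDES


class OverlapPatchEmbed(nn.Module):
    def __init__(self, in_ch: int, embed: int, patch: int, stride: int):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, embed, patch, stride, padding=patch // 2)
        self.norm = nn.LayerNorm(embed)

    def forward(self, x: nn.Tensor):
        x = self.proj(x)
        B, C, H, W = x.shape
        tokens = x.reshape(B, C, H * W).transpose(0, 2, 1)
        return self.norm(tokens), H, W


class SRAttention(nn.Module):
    """Multi-head self-attention with spatial reduction of keys/values."""

    def __init__(self, dim: int, heads: int, sr_ratio: int):
        super().__init__()
        self.heads = heads
        self.dh = dim // heads
        self.scale = self.dh ** -0.5
        self.sr_ratio = sr_ratio
        self.q = nn.Linear(dim, dim)
        self.kv = nn.Linear(dim, 2 * dim)
        self.proj = nn.Linear(dim, dim)
        if sr_ratio > 1:
            self.sr = nn.Conv2d(dim, dim, sr_ratio, sr_ratio)
            self.sr_norm = nn.LayerNorm(dim)

    def forward(self, x: nn.Tensor, H: int, W: int) -> nn.Tensor:
        B, N, C = x.shape
        h, dh = self.heads, self.dh
        q = self.q(x).reshape(B, N, h, dh).transpose(0, 2, 1, 3)
        if self.sr_ratio > 1:
            xm = x.transpose(0, 2, 1).reshape(B, C, H, W)
            xm = self.sr(xm)
            M = xm.shape[2] * xm.shape[3]
            kvs = self.sr_norm(xm.reshape(B, C, M).transpose(0, 2, 1))
        else:
            kvs, M = x, N
        kv = self.kv(kvs).reshape(B, M, 2, h, dh).transpose(2, 0, 3, 1, 4)
        k, v = kv[0], kv[1]
        att = nn.softmax((q @ k.transpose(0, 1, 3, 2)) * self.scale, axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, N, C)
        return self.proj(out)


class ConvMLP(nn.Module):
    """fc -> 3×3 depthwise conv -> GELU -> fc, operating on token matrices."""

    def __init__(self, dim: int, hidden: int):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden)
        self.dw = nn.Conv2d(hidden, hidden, 3, 1, 1, groups=hidden)
        self.fc2 = nn.Linear(hidden, dim)

    def forward(self, x: nn.Tensor, H: int, W: int) -> nn.Tensor:
        x = self.fc1(x)
        B, N, C = x.shape
        m = x.transpose(0, 2, 1).reshape(B, C, H, W)
        m = self.dw(m)
        x = m.reshape(B, C, N).transpose(0, 2, 1)
        return self.fc2(nn.gelu(x))


class Block(nn.Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: int, sr_ratio: int,
                 drop_path: float):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = SRAttention(dim, heads, sr_ratio)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = ConvMLP(dim, dim * mlp_ratio)
        self.drop_path = nn.DropPath(drop_path)

    def forward(self, x: nn.Tensor, H: int, W: int) -> nn.Tensor:
        x = x + self.drop_path(self.attn(self.norm1(x), H, W))
        return x + self.drop_path(self.mlp(self.norm2(x), H, W))


class PVTEncoder(nn.Module):
    def __init__(self, config: EncoderConfig):
        super().__init__()
        self.config = config
        chans = config.channels
        dpr = np.linspace(0.0, config.drop_path_rate, sum(DEPTHS))
        idx = 0
        self.patch_embeds = nn.ModuleList()
        self.stages = nn.ModuleList()
        self.norms = nn.ModuleList()
        in_ch = 3
        for i in range(4):
            patch, stride = (7, 4) if i == 0 else (3, 2)
            self.patch_embeds.append(OverlapPatchEmbed(in_ch, chans[i],
                                                       patch, stride))
            blocks = nn.ModuleList()
            for _ in range(DEPTHS[i]):
                blocks.append(Block(chans[i], HEADS[i], MLP_RATIOS[i],
                                    SR_RATIOS[i], float(dpr[idx])))
                idx += 1
            self.stages.append(blocks)
            self.norms.append(nn.LayerNorm(chans[i]))
            in_ch = chans[i]

    def forward(self, images) -> FeaturePyramid:
        x = images if isinstance(images, nn.Tensor) else nn.Tensor(
            np.asarray(images, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError(f"expected (B, 3, H, W) input, got {x.shape}")
        H, W = x.shape[2], x.shape[3]
        if H % 32 or W % 32:
            raise ShapeError(f"input spatial size must be a multiple of 32, "
                             f"got {H}x{W}")
        maps = []
        for i in range(4):
            tokens, h, w = self.patch_embeds[i](x)
            for blk in self.stages[i]:
                tokens = blk(tokens, h, w)
            tokens = self.norms[i](tokens)
            B, N, C = tokens.shape
            x = tokens.transpose(0, 2, 1).reshape(B, C, h, w)
            maps.append(x)
        return FeaturePyramid(stages=maps)

    def load_pretrained(self, weights: dict[str, np.ndarray]) -> list[str]:
        """Name-matched import of externally supplied weights; returns the
        names that were loaded.  Never required by any test or default
        path."""
        own = dict(self.named_parameters())
        loaded = []
        for name, arr in weights.items():
            if name in own and own[name].data.shape == arr.shape:
                own[name].data = arr.astype(own[name].data.dtype)
                loaded.append(name)
        return loaded


def build_encoder(config: EncoderConfig) -> PVTEncoder:
    """Assemble the encoder; weights are freshly initialised from the
    module RNG (see :func:`rtsnet.nn.seed_all`)."""
    return PVTEncoder(config)


def encode(encoder: PVTEncoder, images) -> FeaturePyramid:
    return encoder(images)
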