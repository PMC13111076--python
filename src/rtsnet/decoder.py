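"""Cascaded decoder: skip fusion, graph convolution, dual-path attention,
learned upsampling, and four deep-supervision heads.

Stage 1 consumes the deepest pyramid level; each stage runs

    GCB -> dual-path attention -> head tap -> UCB (2x upsample)

and the upsampled features are fused with the next-shallower skip by a
1×1 channel-matching convolution plus elementwise addition.  Every head
is a 1×1 convolution to one logit channel, bilinearly upsampled to the
input resolution; the final probability map is the sigmoid of the
merged (mean by default) head logits.  The upsampling block is

    UCB(x) = Conv1x1(ReLU(BN(DWConv3x3(Up2x(x))))).

The shallowest stage's UCB output is taken only for its parameter/shape
contract — heads, not features, carry the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import AttentionConfig, DualPathAttention
from .encoder import EncoderConfig, FeaturePyramid, PVTEncoder, build_encoder
from .errors import ConfigurationError, ShapeError
from .graph import GCBConfig, GraphConvBlock

#: inner GConv width relative to the stage channels; fixed so the full
#: b2 model's trainable parameter count lands on the published 32.25 M.
GCB_HIDDEN_RATIO = 1.75


@dataclass(frozen=True)
class DecoderConfig:
    stage_channels: tuple[int, ...] = (512, 320, 128, 64)   # deep -> shallow
    k_per_stage: tuple[int, ...] = (9, 9, 9, 9)
    heads_per_stage: tuple[int, ...] | None = None   # default channels//64
    fuse_mode: str = "mean"
    residuals: bool = True
    gcb_hidden_ratio: float = GCB_HIDDEN_RATIO
    gcb_variant: str = "max_relative"

    def __post_init__(self):
        if len(self.stage_channels) != 4 or len(self.k_per_stage) != 4:
            raise ConfigurationError("decoder needs exactly 4 stages")
        if self.fuse_mode not in ("sum", "mean"):
            raise ConfigurationError(f"unknown fuse_mode {self.fuse_mode!r}")

    def resolved_heads(self) -> tuple[int, ...]:
        if self.heads_per_stage is not None:
            return tuple(self.heads_per_stage)
        return tuple(max(1, c // 64) for c in self.stage_channels)


@dataclass
class DeepSupervisionOutput:
    """Four per-stage logit maps at input resolution plus their merged
    sigmoid probability."""
    head_logits: list[nn.Tensor]
    fused_probability: nn.Tensor

    def __post_init__(self):
        if len(self.head_logits) != 4:
            raise ShapeError("deep supervision uses exactly 4 heads")


class UCB(nn.Module):
    """Upsampling convolution block: bilinear 2x -> 3×3 depthwise conv ->
    BN -> ReLU -> 1×1 conv to ``out_channels``."""

    def __init__(self, in_channels: int, out_channels: int):
        super().__init__()
        self.dw = nn.Conv2d(in_channels, in_channels, 3, 1, 1,
                            groups=in_channels)
        self.bn = nn.BatchNorm2d(in_channels)
        self.conv = nn.Conv2d(in_channels, out_channels, 1)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        B, C, H, W = x.shape
        up = nn.bilinear_resize(x, 2 * H, 2 * W)
        return self.conv(nn.relu(self.bn(self.dw(up))))


def ucb(x, out_channels: int, module: UCB | None = None) -> nn.Tensor:
    """Functional UCB; builds a fresh block unless one is supplied."""
    m = module if module is not None else UCB(
        x.shape[1] if isinstance(x, nn.Tensor) else np.asarray(x).shape[1],
        out_channels)
    return m(x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x)))


class Decoder(nn.Module):
    def __init__(self, config: DecoderConfig):
        super().__init__()
        self.config = config
        ch = config.stage_channels
        heads = config.resolved_heads()
        self.gcbs = nn.ModuleList()
        self.attns = nn.ModuleList()
        self.heads = nn.ModuleList()
        self.ucbs = nn.ModuleList()
        self.fuses = nn.ModuleList()
        for i in range(4):
            self.gcbs.append(GraphConvBlock(GCBConfig(
                channels=ch[i], k=config.k_per_stage[i],
                conv_variant=config.gcb_variant,
                hidden_ratio=config.gcb_hidden_ratio,
                residual=config.residuals)))
            self.attns.append(DualPathAttention(AttentionConfig(
                channels=ch[i], heads=heads[i])))
            head = nn.Conv2d(ch[i], 1, 1)
            # seg-head convention: small init keeps initial logits near zero
            # (fan-out kaiming is degenerate for a single output channel)
            head.weight.data = nn.get_rng().normal(
                0.0, 0.01, head.weight.data.shape).astype(np.float32)
            self.heads.append(head)
            out_ch = ch[i + 1] if i < 3 else max(ch[3] // 2, 1)
            self.ucbs.append(UCB(ch[i], out_ch))
            if i < 3:
                self.fuses.append(nn.Conv2d(ch[i + 1], ch[i + 1], 1))

    def forward(self, pyramid: FeaturePyramid) -> DeepSupervisionOutput:
        skips = pyramid.stages                       # shallow -> deep
        if tuple(s.shape[1] for s in skips[::-1]) != self.config.stage_channels:
            raise ConfigurationError(
                f"pyramid channels {tuple(s.shape[1] for s in skips[::-1])} "
                f"do not match decoder config {self.config.stage_channels}")
        out_h = skips[0].shape[2] * 4
        out_w = skips[0].shape[3] * 4
        f = skips[3]
        logits = []
        for i in range(4):
            f = self.gcbs[i](f)
            f = self.attns[i](f)
            logits.append(nn.bilinear_resize(self.heads[i](f), out_h, out_w))
            f = self.ucbs[i](f)
            if i < 3:
                f = f + self.fuses[i](skips[2 - i])
        merged = logits[0]
        for l in logits[1:]:
            merged = merged + l
        if self.config.fuse_mode == "mean":
            merged = merged * 0.25
        return DeepSupervisionOutput(head_logits=logits,
                                     fused_probability=nn.sigmoid(merged))


def decode(pyramid: FeaturePyramid, config: DecoderConfig,
           module: Decoder | None = None) -> DeepSupervisionOutput:
    m = module if module is not None else Decoder(config)
    return m(pyramid)


class RTSNet(nn.Module):
    """Full network: hierarchical transformer encoder + cascaded
    graph-convolution / dual-path-attention decoder with deep supervision."""

    def __init__(self, encoder_config: EncoderConfig,
                 decoder_config: DecoderConfig | None = None):
        super().__init__()
        self.encoder_config = encoder_config
        if decoder_config is None:
            decoder_config = DecoderConfig(
                stage_channels=tuple(reversed(encoder_config.channels)))
        self.decoder_config = decoder_config
        self.encoder = build_encoder(encoder_config)
        self.decoder = Decoder(decoder_config)

    def forward(self, images) -> DeepSupervisionOutput:
        return self.decoder(self.encoder(images))


def build_model(variant: str = "b2", drop_path_rate: float = 0.1,
                fuse_mode: str = "mean") -> RTSNet:
    """Assemble the full model for a named variant.

    ``b2`` is the full-scale network (channel widths 64/128/320/512);
    ``tiny`` scales every width by 0.25 for fast CPU experiments.
    """
    if variant == "b2":
        enc = EncoderConfig(variant="b2", drop_path_rate=drop_path_rate)
    elif variant == "tiny":
        enc = EncoderConfig(variant="tiny", width_multiplier=0.25,
                            drop_path_rate=drop_path_rate)
    else:
        raise ConfigurationError(f"unknown model variant {variant!r}")
    dec = DecoderConfig(stage_channels=tuple(reversed(enc.channels)),
                        fuse_mode=fuse_mode)
    return RTSNet(enc, dec)


def rtsnet_forward(images, model: RTSNet) -> DeepSupervisionOutput:
    return model(images)
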