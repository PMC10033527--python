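"""EfficientNet-b0 feature extractor with a non-downsampling stem.

The backbone follows the published b0 layout: a 3x3 stem followed by seven
MBConv stages (mobile inverted bottlenecks with squeeze-and-excitation).
For segmentation the stem runs at stride 1 with 'same' padding, so the
network downsamples 16x overall instead of 32x and the stem feature map
keeps the input resolution.  A 512x512 fundus image therefore yields skip
features at 512/256/128/64 and a 32x32 bottleneck.

The standard classification network (stride-2 stem, 1280-channel top
convolution, 1000-way classifier) can also be built from the same stage
table; it profiles at the published 5.3M parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ConfigurationError, ShapeError
from .nn import tensor as T

#: (block_type, expansion X, kernel size, repeats, output channels, first stride)
B0_STAGE_SPECS: tuple = (
    ("MBConv1", 1, 3, 1, 16, 1),
    ("MBConv6", 6, 3, 2, 24, 2),
    ("MBConv6", 6, 5, 2, 40, 2),
    ("MBConv6", 6, 3, 3, 80, 2),
    ("MBConv6", 6, 5, 3, 112, 1),
    ("MBConv6", 6, 5, 4, 192, 2),
    ("MBConv6", 6, 3, 1, 320, 1),
)

STEM_CHANNELS = 32

#: indices (after which stage) the decoder taps skip features, finest first:
#: the stem output (full resolution) plus the last block of each of the
#: 1/2, 1/4 and 1/8 resolutions; the bottleneck is the final stage output.
SKIP_STAGES = (2, 3, 5)  # 1-based stage indices for the 1/2, 1/4, 1/8 skips


@dataclass
class EncoderConfig:
    stem_kernel: int = 3
    stem_stride: int = 1
    stem_padding: int = 1
    stage_specs: tuple = B0_STAGE_SPECS
    se_reduction: int = 4
    pretrained: bool = False
    weights_path: str | None = None
    seed: int = 0

    def validate(self):
        if self.stem_kernel % 2 != 1:
            raise ConfigurationError("stem kernel must be odd")
        if self.stem_stride != 1:
            raise ConfigurationError("encoder stem must not downsample (stride 1)")
        if self.stem_padding != (self.stem_kernel - 1) // 2:
            raise ConfigurationError("stem padding must preserve spatial size")
        if self.se_reduction < 1:
            raise ConfigurationError("se_reduction must be >= 1")
        for spec in self.stage_specs:
            block, x, k, r, c, s = spec
            if not str(block).startswith("MBConv"):
                raise ConfigurationError(f"unknown block type {block!r}")
            if c <= 0:
                raise ConfigurationError(f"non-positive channel count {c}")
            if s not in (1, 2):
                raise ConfigurationError(f"stage stride must be 1 or 2, got {s}")
            if k not in (3, 5):
                raise ConfigurationError(f"kernel size must be 3 or 5, got {k}")


@dataclass
class EncoderFeatures:
    """Skip features ordered finest first; bottleneck at 1/16 resolution."""

    skips: list
    bottleneck: object

    @property
    def skip_channels(self) -> list[int]:
        return [s.shape[1] for s in self.skips]


class SqueezeExcite(nn.Module):
    """Channel gate: global average pool, two 1x1 convolutions (Swish then
    Sigmoid), multiply back onto the input."""

    def __init__(self, rng, channels: int, squeeze_channels: int):
        super().__init__()
        self.reduce = nn.Conv2d(rng, channels, squeeze_channels, k=1, bias=True)
        self.expand = nn.Conv2d(rng, squeeze_channels, channels, k=1, bias=True)

    def forward(self, x):
        s = T.mean_hw(x)
        s = T.swish(self.reduce(s))
        gate = T.sigmoid(self.expand(s))
        return T.mul(x, gate)

    def macs(self, h, w):
        m1, _ = self.reduce.macs(1, 1)
        m2, _ = self.expand.macs(1, 1)
        return m1 + m2, (h, w)


class MBConv(nn.Module):
    """Mobile inverted bottleneck: 1x1 expansion, k x k depth-wise filter,
    squeeze-and-excitation, 1x1 projection, residual when shape-preserving."""

    def __init__(self, rng, in_ch: int, out_ch: int, k: int, expansion: int,
                 stride: int, se_reduction: int = 4):
        super().__init__()
        if expansion < 1:
            raise ConfigurationError("expansion factor must be >= 1")
        mid = in_ch * expansion
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self.expanded = mid
        self.has_expand = expansion > 1
        if self.has_expand:
            self.expand = nn.Conv2d(rng, in_ch, mid, k=1)
            self.expand_bn = nn.BatchNorm2d(mid)
        self.dw = nn.DepthwiseConv2d(rng, mid, k=k, stride=stride)
        self.dw_bn = nn.BatchNorm2d(mid)
        self.se = SqueezeExcite(rng, mid, max(1, in_ch // se_reduction))
        self.project = nn.Conv2d(rng, mid, out_ch, k=1)
        self.project_bn = nn.BatchNorm2d(out_ch)
        self.use_residual = stride == 1 and in_ch == out_ch

    def forward(self, x):
        if x.shape[1] != self.in_ch:
            raise ShapeError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        h = x
        if self.has_expand:
            h = T.swish(self.expand_bn(self.expand(h)))
        h = T.swish(self.dw_bn(self.dw(h)))
        h = self.se(h)
        h = self.project_bn(self.project(h))
        if self.use_residual:
            h = T.add(h, x)
        return h

    def macs(self, h, w):
        total = 0
        if self.has_expand:
            m, (h2, w2) = self.expand.macs(h, w)
            total += m
        m, (h, w) = self.dw.macs(h, w)
        total += m
        m, _ = self.se.macs(h, w)
        total += m
        m, _ = self.project.macs(h, w)
        total += m
        return total, (h, w)


class EfficientNetEncoder(nn.Module):
    def __init__(self, config: EncoderConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.stem = nn.Conv2d(rng, 3, STEM_CHANNELS, k=config.stem_kernel,
                              stride=config.stem_stride, padding=config.stem_padding)
        self.stem_bn = nn.BatchNorm2d(STEM_CHANNELS)
        in_ch = STEM_CHANNELS
        stages = []
        for si, (block, x, k, r, c, s) in enumerate(config.stage_specs, start=1):
            blocks = []
            for bi in range(r):
                stride = s if bi == 0 else 1
                blocks.append(MBConv(rng, in_ch, c, k, x, stride,
                                     se_reduction=config.se_reduction))
                in_ch = c
            stages.append(nn.Sequential(*blocks))
        self.stages = nn.Sequential(*stages)
        self.out_channels = in_ch

    @property
    def skip_channel_counts(self) -> list[int]:
        counts = [STEM_CHANNELS]
        for idx in SKIP_STAGES:
            counts.append(self.config.stage_specs[idx - 1][4])
        return counts

    def forward(self, x) -> EncoderFeatures:
        x = T.as_tensor(x)
        n, c, h, w = x.shape
        if h % 16 or w % 16:
            raise ShapeError(
                f"input spatial size {h}x{w} must be divisible by 16 "
                "(stride-1 stem followed by four stride-2 stages)")
        s = T.swish(self.stem_bn(self.stem(x)))
        skips = [s]
        out = s
        for i, stage in enumerate(self.stages, start=1):
            out = stage(out)
            if i in SKIP_STAGES:
                skips.append(out)
        return EncoderFeatures(skips=skips, bottleneck=out)

    def macs(self, h, w):
        total, (h, w) = self.stem.macs(h, w)
        m, (h, w) = self.stages.macs(h, w)
        return total + m, (h, w)


class EfficientNetB0Classifier(nn.Module):
    """The unmodified classification network (stride-2 stem, 1000 classes)."""

    def __init__(self, seed: int = 0, num_classes: int = 1000):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.stem = nn.Conv2d(rng, 3, STEM_CHANNELS, k=3, stride=2, padding=1)
        self.stem_bn = nn.BatchNorm2d(STEM_CHANNELS)
        in_ch = STEM_CHANNELS
        stages = []
        for block, x, k, r, c, s in B0_STAGE_SPECS:
            blocks = []
            for bi in range(r):
                blocks.append(MBConv(rng, in_ch, c, k, x, s if bi == 0 else 1))
                in_ch = c
            stages.append(nn.Sequential(*blocks))
        self.stages = nn.Sequential(*stages)
        self.top = nn.Conv2d(rng, in_ch, 1280, k=1)
        self.top_bn = nn.BatchNorm2d(1280)
        self.classifier = nn.Linear(rng, 1280, num_classes, bias=True)

    def forward(self, x):
        h = T.swish(self.stem_bn(self.stem(T.as_tensor(x))))
        h = self.stages(h)
        h = T.swish(self.top_bn(self.top(h)))
        h = T.mean_hw(h)
        h = T.reshape(h, (h.shape[0], 1280))
        return self.classifier(h)

    def macs(self, h, w):
        total, (h, w) = self.stem.macs(h, w)
        m, (h, w) = self.stages.macs(h, w)
        total += m
        m, _ = self.top.macs(h, w)
        total += m
        m, _ = self.classifier.macs(1, 1)
        return total + m, (1, 1)


def build_encoder(config: EncoderConfig | None = None) -> EfficientNetEncoder:
    """Build the modified-stem b0 encoder.

    With ``pretrained=True`` a ``weights_path`` (npz state dict in this
    package's naming) must be supplied; tensors whose stored shape does not
    match the modified architecture are left at their seeded initialization.
    """
    config = config or EncoderConfig()
    enc = EfficientNetEncoder(config)
    if config.pretrained:
        if not config.weights_path:
            raise ConfigurationError(
                "pretrained=True requires weights_path (no network access)")
        state = dict(np.load(config.weights_path))
        compatible = {}
        own = enc.state_dict()
        for k, v in state.items():
            if k in own and own[k].shape == np.asarray(v).shape:
                compatible[k] = v
        enc.load_state_dict({**own, **compatible})
    return enc


def build_b0_classifier(seed: int = 0) -> EfficientNetB0Classifier:
    return EfficientNetB0Classifier(seed=seed)
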