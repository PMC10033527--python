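"""The full segmentation network: EfficientNet-b0 encoder, wide bottleneck
projection, attention-gated skips and a residual depth-wise separable
convolution (RDSC) decoder, ending in a per-pixel softmax over the three
classes {background, disc rim, cup}.

Width calibration.  The architecture diagram of EARDS fixes the wiring but
not the widths; the widths used here were calibrated once so that the
profiler reproduces the published complexity profile of the EARDS family
(15.44M parameters; 17.14M with standard convolutions in place of RDSC;
15.28M without attention gates).  That profile pins most of the capacity
into the 1x1 bottleneck projection (320 -> 2954 -> 3456 channels at 1/16
resolution) and keeps the per-level decoder narrow (64, 48, 32, 24, 16).
See docs/methods.md for the calibration reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .blocks import AttentionGate, RDSCBlock, StandardConvBlock
from .encoder import EncoderConfig, EfficientNetEncoder, STEM_CHANNELS
from .exceptions import ConfigurationError, ShapeError
from .nn import tensor as T

#: calibrated defaults (see module docstring)
DEFAULT_DECODER_CHANNELS = (64, 48, 32, 24, 16)
DEFAULT_BRIDGE_CHANNELS = (2954, 3456)
DEFAULT_ATTENTION_CHANNELS = (44, 24, 16, 16)


@dataclass
class ModelConfig:
    input_size: int = 512
    num_classes: int = 3
    decoder_channels: tuple = DEFAULT_DECODER_CHANNELS
    bridge_channels: tuple = DEFAULT_BRIDGE_CHANNELS
    attention_channels: tuple = DEFAULT_ATTENTION_CHANNELS
    use_attention: bool = True
    use_rdsc: bool = True
    seed: int = 0
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def validate(self):
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if len(self.decoder_channels) != 5:
            raise ConfigurationError(
                "decoder_channels must list 5 widths (number of skips + 1), "
                f"got {len(self.decoder_channels)}")
        if self.use_attention and len(self.attention_channels) != 4:
            raise ConfigurationError("attention_channels must list 4 widths")
        if len(self.bridge_channels) != 2:
            raise ConfigurationError("bridge_channels must list 2 widths")
        for c in (*self.decoder_channels, *self.bridge_channels):
            if c <= 0:
                raise ConfigurationError(f"non-positive channel count {c}")

    @staticmethod
    def small(num_classes: int = 3, seed: int = 0) -> "ModelConfig":
        """A narrow configuration for desk-scale experiments: same topology,
        lightweight bottleneck projection and decoder."""
        return ModelConfig(
            input_size=128,
            num_classes=num_classes,
            decoder_channels=(64, 48, 32, 24, 16),
            bridge_channels=(96, 64),
            attention_channels=(16, 16, 8, 8),
            seed=seed,
        )


class EARDS(nn.Module):
    """Encoder-decoder segmentation network producing per-pixel class
    probabilities (channels sum to one at every pixel)."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        config = config or ModelConfig()
        config.validate()
        self.config = config
        enc_cfg = config.encoder
        if enc_cfg.seed != config.seed:
            enc_cfg = EncoderConfig(**{**enc_cfg.__dict__, "seed": config.seed})
        self.encoder = EfficientNetEncoder(enc_cfg)
        rng = np.random.default_rng(config.seed + 1)

        bw, bout = config.bridge_channels
        bottleneck_ch = self.encoder.out_channels
        self.bridge = nn.Sequential(
            nn.Conv2d(rng, bottleneck_ch, bw, k=1), nn.BatchNorm2d(bw), nn.Swish(),
            nn.Conv2d(rng, bw, bout, k=1), nn.BatchNorm2d(bout), nn.Swish(),
        )

        # skip channels finest-first from the encoder; the decoder consumes
        # them coarsest-first
        skips_fine_first = self.encoder.skip_channel_counts
        self.skip_channels = skips_fine_first[::-1]          # [112, 40, 24, 32]

        cs = config.decoder_channels
        gate_channels = [bout, cs[0], cs[1], cs[2]]
        if config.use_attention:
            self.gates = nn.Sequential(*[
                AttentionGate(rng, skip_ch, gate_ch, inter_ch)
                for skip_ch, gate_ch, inter_ch in
                zip(self.skip_channels, gate_channels, config.attention_channels)])
        else:
            self.gates = None

        block_cls = RDSCBlock if config.use_rdsc else StandardConvBlock
        ins = [bout + self.skip_channels[0],
               cs[0] + self.skip_channels[1],
               cs[1] + self.skip_channels[2],
               cs[2] + self.skip_channels[3],
               cs[3]]
        self.decoder = nn.Sequential(*[
            block_cls(rng, m, n) for m, n in zip(ins, cs)])
        self.up = nn.UpsampleBilinear(2)
        self.head = nn.Conv2d(rng, cs[4], config.num_classes, k=1, bias=True)

    def forward(self, image):
        """Image (N,3,H,W) with H, W divisible by 16 -> probabilities (N,K,H,W)."""
        feats = self.encoder(image)
        d = self.bridge(feats.bottleneck)
        skips_coarse_first = feats.skips[::-1]
        blocks = list(self.decoder)
        gates = list(self.gates) if self.gates is not None else [None] * 4
        for i, skip in enumerate(skips_coarse_first):
            gated = skip if gates[i] is None else gates[i](skip, d)
            d = self.up(d)
            d = blocks[i](T.concat([d, gated], axis=1))
        d = blocks[4](d)
        return T.softmax_channels(self.head(d))

    # -- complexity ----------------------------------------------------------
    def profile_components(self, size: int):
        """Per-component (name, params, macs) at a given input size."""
        if size % 16:
            raise ShapeError(f"input size {size} must be divisible by 16")
        comps = []
        enc_macs, _ = self.encoder.macs(size, size)
        comps.append(("encoder", self.encoder.num_parameters(), enc_macs))
        s16 = size // 16
        bridge_macs, _ = self.bridge.macs(s16, s16)
        comps.append(("bridge", self.bridge.num_parameters(), bridge_macs))
        skip_sizes = [size // 8, size // 4, size // 2, size]
        if self.gates is not None:
            gm = sum(g.macs(s, s)[0] for g, s in zip(self.gates, skip_sizes))
            comps.append(("attention_gates", self.gates.num_parameters(), gm))
        blocks = list(self.decoder)
        dm = sum(b.macs(s, s)[0] for b, s in zip(blocks, skip_sizes))
        dm += blocks[4].macs(size, size)[0]
        comps.append(("decoder", self.decoder.num_parameters(), dm))
        head_macs, _ = self.head.macs(size, size)
        comps.append(("head", self.head.num_parameters(), head_macs))
        return comps

    def macs(self, h, w):
        if h != w:
            raise ShapeError("profiling assumes square inputs")
        return sum(m for _, _, m in self.profile_components(h)), (h, w)


def build_eards(config: ModelConfig | None = None) -> EARDS:
    return EARDS(config)


def predict_masks(probmap: np.ndarray):
    """Decode a probability map into (label_mask, disc_mask, cup_mask).

    label_mask: per-pixel argmax with ties broken toward the lowest class
    index (background).  The disc is the anatomical union rim + cup; the cup
    mask is the cup class alone, so cup pixels belong to both masks.
    """
    p = np.asarray(probmap)
    if p.ndim == 4:
        if p.shape[0] != 1:
            raise ShapeError("predict_masks expects a single image")
        p = p[0]
    label = np.argmax(p, axis=0).astype(np.uint8)
    disc = label >= 1
    cup = label == 2
    return label, disc, cup
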