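"""Attention gates, residual depth-wise separable convolution blocks, and
the analytic multiplication-cost formulas for standard vs. separable
convolutions.

Cost accounting.  For a stride-1, padding-1 convolution producing a
D_F x D_F map from M input channels with a D_K x D_K kernel and N output
channels, the number of scalar multiplications is

    standard:     D_K^2 * M * N * D_F^2
    depth-wise:   D_K^2 * M * D_F^2
    separable:    D_K^2 * M * D_F^2  +  M * N * D_F^2

so the separable/standard ratio is 1/N + 1/D_K^2 — the saving that
motivates replacing the decoder's standard convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .exceptions import ConfigurationError, ShapeError
from .nn import tensor as T


@dataclass(frozen=True)
class ConvCostSpec:
    """Kernel size D_K, feature-map size D_F, input channels M, output channels N."""

    d_k: int
    d_f: int
    m: int
    n: int

    def validate(self):
        for name, v in (("d_k", self.d_k), ("d_f", self.d_f),
                        ("m", self.m), ("n", self.n)):
            if int(v) != v or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v}")


def standard_conv_cost(spec: ConvCostSpec) -> int:
    """Multiplications of a standard convolution (stride 1, padding 1)."""
    spec.validate()
    return spec.d_k * spec.d_k * spec.m * spec.n * spec.d_f * spec.d_f


def depthwise_conv_cost(spec: ConvCostSpec) -> int:
    """Multiplications of the depth-wise stage alone."""
    spec.validate()
    return spec.d_k * spec.d_k * spec.m * spec.d_f * spec.d_f


def dsc_cost(spec: ConvCostSpec) -> int:
    """Multiplications of a depth-wise separable convolution
    (depth-wise filter + 1x1 point-wise combination)."""
    spec.validate()
    return depthwise_conv_cost(spec) + spec.m * spec.n * spec.d_f * spec.d_f


class AttentionGate(nn.Module):
    """Additive attention on a skip connection.

    The gating signal ``g`` (coarser decoder state) and the skip features
    ``x_l`` are each mapped through a 1x1 convolution with batch
    normalization; the g-branch is bilinearly resampled to the skip
    resolution, the branches are summed, rectified, squeezed to a single
    channel and squashed to the attention coefficient alpha in (0, 1),
    which multiplicatively reweights the skip features.
    """

    def __init__(self, rng, skip_ch: int, gate_ch: int, inter_ch: int):
        super().__init__()
        if inter_ch <= 0:
            raise ConfigurationError("inter_channels must be positive")
        self.skip_ch, self.gate_ch, self.inter_ch = skip_ch, gate_ch, inter_ch
        self.theta_x = nn.Conv2d(rng, skip_ch, inter_ch, k=1)
        self.theta_x_bn = nn.BatchNorm2d(inter_ch)
        self.theta_g = nn.Conv2d(rng, gate_ch, inter_ch, k=1)
        self.theta_g_bn = nn.BatchNorm2d(inter_ch)
        self.psi = nn.Conv2d(rng, inter_ch, 1, k=1, bias=True)

    def forward(self, x_l, g):
        if x_l.shape[0] != g.shape[0]:
            raise ShapeError("skip and gating tensors must share the batch size")
        if g.shape[2] > x_l.shape[2] or g.shape[3] > x_l.shape[3]:
            raise ShapeError("gating signal must not be finer than the skip")
        xb = self.theta_x_bn(self.theta_x(x_l))
        gb = self.theta_g_bn(self.theta_g(g))
        if gb.shape[2:] != x_l.shape[2:]:
            gb = T.upsample_bilinear(gb, x_l.shape[2], x_l.shape[3])
        alpha = T.sigmoid(self.psi(T.relu(T.add(xb, gb))))
        return T.mul(x_l, alpha)

    def attention_map(self, x_l, g):
        """The attention coefficients alpha at the skip resolution."""
        xb = self.theta_x_bn(self.theta_x(x_l))
        gb = self.theta_g_bn(self.theta_g(g))
        if gb.shape[2:] != x_l.shape[2:]:
            gb = T.upsample_bilinear(gb, x_l.shape[2], x_l.shape[3])
        return T.sigmoid(self.psi(T.relu(T.add(xb, gb)))).data

    def macs(self, h, w):
        """MACs with the skip at h x w and the gate at h/2 x w/2."""
        mx, _ = self.theta_x.macs(h, w)
        mg, _ = self.theta_g.macs(h // 2, w // 2)
        mp, _ = self.psi.macs(h, w)
        return mx + mg + mp, (h, w)


class RDSCBlock(nn.Module):
    """Residual depth-wise separable convolution block.

    Main path: 3x3 depth-wise convolution -> BN -> ReLU -> 1x1 point-wise
    convolution -> BN -> ReLU.  Residual path: identity when the channel
    count is preserved, otherwise a 1x1 channel convolution (CC) with BN.
    The two paths are summed with no post-sum activation.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, k: int = 3):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.dw = nn.DepthwiseConv2d(rng, in_ch, k=k)
        self.dw_bn = nn.BatchNorm2d(in_ch)
        self.pw = nn.Conv2d(rng, in_ch, out_ch, k=1)
        self.pw_bn = nn.BatchNorm2d(out_ch)
        if in_ch != out_ch:
            self.cc = nn.Conv2d(rng, in_ch, out_ch, k=1)
            self.cc_bn = nn.BatchNorm2d(out_ch)
        else:
            self.cc = None

    def forward(self, x):
        h = T.relu(self.dw_bn(self.dw(x)))
        h = T.relu(self.pw_bn(self.pw(h)))
        res = x if self.cc is None else self.cc_bn(self.cc(x))
        return T.add(h, res)

    def macs(self, h, w):
        m, _ = self.dw.macs(h, w)
        mp, _ = self.pw.macs(h, w)
        m += mp
        if self.cc is not None:
            mc, _ = self.cc.macs(h, w)
            m += mc
        return m, (h, w)


class StandardConvBlock(nn.Module):
    """The non-separable counterpart: two 3x3 convolutions (each BN + ReLU)
    with the same channel plan as the RDSC block it replaces."""

    def __init__(self, rng, in_ch: int, out_ch: int):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.conv1 = nn.Conv2d(rng, in_ch, out_ch, k=3)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(rng, out_ch, out_ch, k=3)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        h = T.relu(self.bn1(self.conv1(x)))
        return T.relu(self.bn2(self.conv2(h)))

    def macs(self, h, w):
        m1, _ = self.conv1.macs(h, w)
        m2, _ = self.conv2.macs(h, w)
        return m1 + m2, (h, w)
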