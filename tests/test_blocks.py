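"""Convolution cost formulas (with brute-force multiplication oracles),
attention gate semantics and RDSC block behaviour."""

import numpy as np
import pytest

from eards.blocks import (
    AttentionGate,
    ConvCostSpec,
    RDSCBlock,
    StandardConvBlock,
    depthwise_conv_cost,
    dsc_cost,
    standard_conv_cost,
)
from eards.exceptions import ConfigurationError
from eards.nn import tensor as T


def brute_force_conv_multiplies(d_k, d_f, m, n):
    """Count multiplications of an explicit stride-1 'same' convolution loop
    over a d_f x d_f map (each output pixel: d_k^2 kernel taps x m inputs,
    for each of n output channels)."""
    count = 0
    for _out_ch in range(n):
        for _y in range(d_f):
            for _x in range(d_f):
                count += d_k * d_k * m
    return count


def brute_force_dsc_multiplies(d_k, d_f, m, n):
    depthwise = 0
    for _ch in range(m):
        for _y in range(d_f):
            for _x in range(d_f):
                depthwise += d_k * d_k
    pointwise = brute_force_conv_multiplies(1, d_f, m, n)
    return depthwise + pointwise


@pytest.mark.parametrize("spec,expected_std,expected_dsc", [
    (ConvCostSpec(d_k=3, d_f=1, m=1, n=1), 9, None),
    (ConvCostSpec(d_k=3, d_f=8, m=16, n=32), 294912, 41984),
    (ConvCostSpec(d_k=1, d_f=2, m=5, n=7), 140, None),
    (ConvCostSpec(d_k=1, d_f=1, m=3, n=3), None, 12),
])
def test_cost_formulas_match_frozen_values_and_oracle(spec, expected_std, expected_dsc):
    std = standard_conv_cost(spec)
    sep = dsc_cost(spec)
    assert std == brute_force_conv_multiplies(spec.d_k, spec.d_f, spec.m, spec.n)
    assert sep == brute_force_dsc_multiplies(spec.d_k, spec.d_f, spec.m, spec.n)
    if expected_std is not None:
        assert std == expected_std
    if expected_dsc is not None:
        assert sep == expected_dsc


def test_cost_ratio_identity():
    spec = ConvCostSpec(d_k=3, d_f=8, m=16, n=32)
    ratio = dsc_cost(spec) / standard_conv_cost(spec)
    assert ratio == pytest.approx(1 / spec.n + 1 / spec.d_k ** 2, abs=1e-12)
    assert ratio == pytest.approx(0.14236, abs=5e-6)


def test_dsc_always_cheaper_when_meaningful():
    rng = np.random.default_rng(0)
    for _ in range(200):
        spec = ConvCostSpec(d_k=int(rng.choice([3, 5])),
                            d_f=int(rng.integers(1, 16)),
                            m=int(rng.integers(1, 64)),
                            n=int(rng.integers(2, 64)))
        assert dsc_cost(spec) < standard_conv_cost(spec)


def test_cost_spec_rejects_nonpositive():
    with pytest.raises(ConfigurationError):
        standard_conv_cost(ConvCostSpec(d_k=0, d_f=4, m=1, n=1))


def test_depthwise_cost_is_first_term_of_dsc():
    spec = ConvCostSpec(d_k=3, d_f=8, m=16, n=32)
    assert depthwise_conv_cost(spec) == 9216
    assert dsc_cost(spec) - depthwise_conv_cost(spec) == 16 * 32 * 64


class TestAttentionGate:
    def _gate(self, rng, skip_ch=4, gate_ch=6, inter=5):
        return AttentionGate(rng, skip_ch, gate_ch, inter)

    def test_unit_gate_passes_skip_through(self, rng):
        ag = self._gate(rng)
        ag.eval()
        # force alpha ~ 1: psi weights 0 and a large positive bias
        ag.psi.weight.data[:] = 0.0
        ag.psi.bias.data[:] = 50.0
        x = T.Tensor(rng.normal(size=(2, 4, 8, 8)))
        g = T.Tensor(rng.normal(size=(2, 6, 4, 4)))
        np.testing.assert_allclose(ag(x, g).data, x.data, rtol=1e-5, atol=1e-6)

    def test_closed_gate_suppresses_skip(self, rng):
        ag = self._gate(rng)
        ag.eval()
        ag.psi.weight.data[:] = 0.0
        ag.psi.bias.data[:] = -50.0
        x = T.Tensor(rng.normal(size=(1, 4, 8, 8)))
        g = T.Tensor(rng.normal(size=(1, 6, 4, 4)))
        assert np.abs(ag(x, g).data).max() < 1e-6

    def test_output_bounded_by_nonnegative_skip(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            ag = AttentionGate(r, 3, 5, 4)
            ag.eval()
            x = T.Tensor(r.random((1, 3, 8, 8)))
            g = T.Tensor(r.normal(size=(1, 5, 4, 4)))
            out = ag(x, g).data
            assert (out >= 0).all() and (out <= x.data + 1e-7).all()

    def test_alpha_in_open_interval_and_shape_preserved(self, rng):
        ag = self._gate(rng)
        ag.eval()
        x = T.Tensor(rng.normal(size=(2, 4, 8, 8)))
        g = T.Tensor(rng.normal(size=(2, 6, 4, 4)))
        alpha = ag.attention_map(x, g)
        assert alpha.shape == (2, 1, 8, 8)
        assert (alpha > 0).all() and (alpha < 1).all()
        assert ag(x, g).shape == x.shape

    def test_gradients_flow_to_both_inputs(self, rng):
        ag = self._gate(rng)
        ag.train()
        x = T.Tensor(rng.normal(size=(1, 4, 8, 8)), requires_grad=True)
        g = T.Tensor(rng.normal(size=(1, 6, 4, 4)), requires_grad=True)
        T.tsum(T.mul(ag(x, g), 1.0)).backward()
        assert x.grad is not None and np.abs(x.grad).sum() > 0
        assert g.grad is not None and np.abs(g.grad).sum() > 0

    def test_batch_mismatch_raises(self, rng):
        ag = self._gate(rng)
        from eards.exceptions import ShapeError
        with pytest.raises(ShapeError):
            ag(T.Tensor(np.zeros((2, 4, 8, 8))), T.Tensor(np.zeros((1, 6, 4, 4))))


class TestRDSC:
    def test_pure_residual_when_main_branch_zeroed(self, rng):
        blk = RDSCBlock(rng, 6, 6)
        blk.eval()
        blk.pw.weight.data[:] = 0.0      # kills the main path output
        x = T.Tensor(rng.normal(size=(2, 6, 5, 5)))
        np.testing.assert_allclose(blk(x).data, x.data, rtol=1e-6)

    def test_shape_contract(self, rng):
        blk = RDSCBlock(rng, 16, 32)
        blk.eval()
        out = blk(T.Tensor(np.zeros((1, 16, 64, 64), dtype=np.float32)))
        assert out.shape == (1, 32, 64, 64)

    def test_parameter_count_matches_brute_force_enumeration(self, rng):
        blk = RDSCBlock(rng, 16, 32)
        manual = (
            16 * 3 * 3          # depth-wise
            + 2 * 16            # BN
            + 16 * 32           # point-wise
            + 2 * 32            # BN
            + 16 * 32           # channel convolution (16 != 32)
            + 2 * 32            # BN
        )
        assert blk.num_parameters() == manual
        assert blk.num_parameters() == sum(p.data.size for p in blk.parameters())

    def test_residual_connectivity_with_zeroed_main_branch(self, rng):
        blk = RDSCBlock(rng, 4, 8)
        blk.eval()
        blk.pw.weight.data[:] = 0.0
        x1 = np.zeros((1, 4, 6, 6), dtype=np.float32)
        x2 = x1.copy(); x2[0, 2, 3, 3] = 1.0
        y1, y2 = blk(T.Tensor(x1)).data, blk(T.Tensor(x2)).data
        assert np.abs(y1 - y2).max() > 0   # input reaches output via residual

    def test_standard_block_parameter_plan(self, rng):
        blk = StandardConvBlock(rng, 16, 32)
        assert blk.num_parameters() == 9 * 16 * 32 + 2 * 32 + 9 * 32 * 32 + 2 * 32
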