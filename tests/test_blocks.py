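"""Contracts and dual-route (vectorized vs straight-loop) checks for the
three context blocks."""

import numpy as np
import pytest

from frcnet import nn
from frcnet.blocks import (ECCBlock, ECCConfig, MPABlock, MPAConfig, PCFBlock,
                           PCFConfig, context_calibrate, ecc_forward,
                           mpa_forward, pcf_forward, se_reweight)

from _oracles import (o_ecc_calibrate, o_ecc_forward, o_gap, o_mpa_forward,
                      o_pcf_forward, o_se_gate)


def _ecc(channels=4, rate=2, seed=1, **kw):
    return ECCBlock(ECCConfig(channels, rate), np.random.default_rng(seed),
                    dtype=np.float64, **kw)


def _pcf(channels=4, dilation=2, ratio=2, seed=2):
    return PCFBlock(PCFConfig(channels, dilation, ratio),
                    np.random.default_rng(seed), dtype=np.float64)


def _mpa(levels=(4, 4, 4, 4, 4), fused=8, se=4, seed=3):
    return MPABlock(MPAConfig(levels, fused, se), np.random.default_rng(seed),
                    dtype=np.float64)


# -- configuration validation ------------------------------------------------

@pytest.mark.parametrize("bad", [
    lambda: ECCConfig(5),                      # odd channels
    lambda: ECCConfig(4, calibration_rate=3),  # not a power of two
    lambda: ECCConfig(4, calibration_rate=1),
    lambda: PCFConfig(5),
    lambda: PCFConfig(8, bottleneck_ratio=3),  # does not divide channels
    lambda: MPAConfig((4, 4, 4, 4)),           # wrong level count
    lambda: MPAConfig(fused_channels=30, se_ratio=4),
])
def test_invalid_configurations_are_rejected(bad):
    with pytest.raises(ValueError):
        bad()


def test_ecc_rejects_wrong_channels_and_indivisible_sizes(rng):
    block = _ecc(4, 2)
    with pytest.raises(ValueError):
        block(rng.normal(size=(1, 6, 8, 8)))
    with pytest.raises(ValueError, match="height"):
        block(rng.normal(size=(1, 4, 7, 8)))
    with pytest.raises(ValueError, match="width"):
        block(rng.normal(size=(1, 4, 8, 9)))


def test_mpa_rejects_wrong_level_count_and_oversized_levels(rng):
    block = _mpa()
    levels = [rng.normal(size=(1, 4, 8, 8)) for _ in range(5)]
    with pytest.raises(ValueError):
        mpa_forward(levels[:4], block)
    levels[2] = rng.normal(size=(1, 4, 16, 16))  # coarser level larger than l0
    with pytest.raises(ValueError):
        mpa_forward(levels, block)


# -- shape and range contracts ----------------------------------------------

@pytest.mark.parametrize("shape", [(2, 16, 32, 32), (1, 4, 8, 8), (3, 8, 16, 24)])
def test_ecc_and_pcf_preserve_shape(shape, rng):
    x = rng.normal(size=shape)
    assert ecc_forward(x, _ecc(shape[1], 2)).shape == shape
    assert pcf_forward(x, _pcf(shape[1])).shape == shape


def test_ecc_zero_input_is_fixed_point_with_biasfree_weights():
    block = _ecc(4, 2, bias=False)
    out = ecc_forward(np.zeros((1, 4, 8, 8)), block)
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_calibration_map_is_strict_sigmoid_range(rng):
    block = _ecc(8, 2)
    att = context_calibrate(rng.normal(size=(2, 4, 8, 8)), block)
    assert att.min() > 0.0 and att.max() < 1.0
    # zero input through zero-initialized convolutions gives sigma(0) = 1/2
    zero_block = _ecc(4, 2, bias=False)
    for p in zero_block.calibration.parameters():
        p.data = np.zeros_like(p.data)
    att0 = context_calibrate(np.zeros((1, 2, 4, 4)), zero_block)
    np.testing.assert_allclose(att0, 0.5, atol=1e-12)


def test_pcf_attention_weights_sum_to_one(rng):
    block = _pcf(8, dilation=3, ratio=4)
    beta = block.attention_weights(rng.normal(size=(3, 8, 6, 6)))
    np.testing.assert_allclose(beta.reshape(3, -1).sum(axis=1), 1.0, atol=1e-6)


def test_mpa_shape_contract_and_gate_range(rng):
    cfg = [(1, 16, 64, 64), (1, 32, 32, 32), (1, 64, 16, 16),
           (1, 128, 8, 8), (1, 160, 4, 4)]
    block = MPABlock(MPAConfig((16, 32, 64, 128, 160), 32, 4),
                     np.random.default_rng(0), dtype=np.float64)
    levels = [rng.normal(size=s) for s in cfg]
    out = mpa_forward(levels, block)
    assert out.shape == (1, 32, 64, 64)
    gate = se_reweight(rng.normal(size=32), block)
    assert gate.shape == (32,)
    assert gate.min() > 0.0 and gate.max() < 1.0


def test_se_gate_of_zero_vector_is_half_with_zero_weights():
    block = _mpa(fused=8, se=4)
    for p in (*block.fc1.parameters(), *block.fc2.parameters()):
        p.data = np.zeros_like(p.data)
    np.testing.assert_allclose(se_reweight(np.zeros(8), block), 0.5)


# -- dual-route oracle equivalence -------------------------------------------

def test_ecc_matches_straight_loop_composition(rng):
    block = _ecc(4, 2, seed=9)
    x = rng.normal(size=(1, 4, 8, 8))
    np.testing.assert_allclose(ecc_forward(x, block), o_ecc_forward(block, x),
                               rtol=1e-5, atol=1e-8)


def test_calibration_matches_loop_oracle(rng):
    block = _ecc(8, 2, seed=4)
    x2 = rng.normal(size=(1, 4, 8, 8))
    np.testing.assert_allclose(context_calibrate(x2, block),
                               o_ecc_calibrate(block, x2), rtol=1e-5, atol=1e-8)


def test_pcf_matches_attention_pooling_oracle(rng):
    block = _pcf(4, dilation=2, ratio=2, seed=5)
    x = rng.normal(size=(1, 4, 6, 6))
    np.testing.assert_allclose(pcf_forward(x, block), o_pcf_forward(block, x),
                               rtol=1e-5, atol=1e-8)


def test_mpa_matches_gap_and_dense_oracles(rng):
    block = _mpa(seed=6)
    levels = [rng.normal(size=(1, 4, 4, 4)), rng.normal(size=(1, 4, 2, 2)),
              rng.normal(size=(1, 4, 2, 2)), rng.normal(size=(1, 4, 1, 1)),
              rng.normal(size=(1, 4, 1, 1))]
    np.testing.assert_allclose(mpa_forward(levels, block),
                               o_mpa_forward(block, levels), rtol=1e-5, atol=1e-8)
    g = rng.normal(size=(1, 8, 4, 4))
    np.testing.assert_allclose(
        nn.global_avg_pool(nn.Tensor(g)).data, o_gap(g), rtol=1e-12)
    v = rng.normal(size=8)
    np.testing.assert_allclose(se_reweight(v, block), o_se_gate(block, v),
                               rtol=1e-5, atol=1e-10)


# -- numerical properties -----------------------------------------------------

def test_blocks_emit_finite_values_and_are_deterministic(rng):
    x = rng.normal(size=(2, 8, 8, 8))
    for make in (lambda: _ecc(8, 2, seed=10), lambda: _pcf(8, 3, 4, seed=10)):
        out1 = make()(nn.Tensor(x)).data
        out2 = make()(nn.Tensor(x)).data
        assert np.isfinite(out1).all()
        assert np.array_equal(out1, out2)


def test_block_gradients_match_finite_differences(rng):
    """End-to-end differentiability of each block on a tiny instance."""
    x = rng.normal(size=(1, 4, 4, 4))

    def loss_of(block_fn, v):
        out = block_fn(nn.Tensor(v))
        return float((out.data ** 2).sum())

    for block in (_ecc(4, 2, seed=11),
                  _pcf(4, dilation=1, ratio=2, seed=12)):
        xt = nn.Tensor(x.copy(), requires_grad=True)
        out = block(xt)
        nn.core.sum_(out * out).backward()
        num = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            xp, xm = x.copy(), x.copy()
            xp[i] += 1e-5
            xm[i] -= 1e-5
            num[i] = (loss_of(block, xp) - loss_of(block, xm)) / 2e-5
        np.testing.assert_allclose(xt.grad, num, rtol=1e-3, atol=1e-6)
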