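"""Attention-block contracts: shapes, bounds, analytic parameter counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strawdet import nn
from strawdet.blocks import (CGFM, CGFMConfig, MSDWAConfig, MultiHeadSelfAttention,
                             SEConfig, SEMSDWA, SqueezeExcite, cgfm_param_count,
                             msdwa_param_count)

# widths of the four neck fusion nodes at scale s, and the calibrated
# attention dims; together they set the block's parameter budget
NECK_NODES_S = [(512, 256, 624), (256, 128, 320), (128, 256, 320), (256, 512, 624)]


# ---------------------------------------------------------------------------
# squeeze-and-excitation
# ---------------------------------------------------------------------------

def test_se_zero_input_gives_zero_output():
    se = SqueezeExcite(SEConfig(8, 4))
    out = se(nn.Tensor(np.zeros((2, 8, 5, 5), np.float32)))
    assert np.all(out.data == 0)


def test_se_attenuates_every_channel(rng):
    se = SqueezeExcite(SEConfig(16, 4))
    x = rng.normal(size=(2, 16, 6, 6)).astype(np.float32)
    out = se(nn.Tensor(x))
    assert np.all(np.abs(out.data) <= np.abs(x) + 1e-7)
    assert out.data.shape == x.shape


def test_se_parameter_count_closed_form():
    # C=64, r=16 with biases: 64*4+4 + 4*64+64 = 580
    se = SqueezeExcite(SEConfig(64, 16))
    assert se.num_parameters() == 580


def test_se_channel_mismatch_raises(rng):
    se = SqueezeExcite(SEConfig(8, 2))
    with pytest.raises(ValueError):
        se(nn.Tensor(rng.normal(size=(1, 4, 3, 3)).astype(np.float32)))


# ---------------------------------------------------------------------------
# SE-MSDWA
# ---------------------------------------------------------------------------

def test_msdwa_preserves_shape(rng):
    blk = SEMSDWA(MSDWAConfig(32, se=SEConfig(32, 4)))
    x = rng.normal(size=(2, 32, 20, 20)).astype(np.float32)
    assert blk(nn.Tensor(x)).data.shape == x.shape


def test_msdwa_reference_parameter_count():
    # C=64, r=16, 5x5 depthwise: 1664 + 768+1280+2304 + 4160 + 580 = 10756
    cfg = MSDWAConfig(64, se=SEConfig(64, 16))
    assert msdwa_param_count(cfg) == 10756
    assert SEMSDWA(cfg).num_parameters() == 10756


def test_msdwa_degenerate_smallest_config():
    cfg = MSDWAConfig(1, dw_kernel=1, strip_kernels=(1,), se=SEConfig(1, 1))
    # dw 1x1: 2; strip pair (1,1)+(1,1): 4; pointwise: 2; SE: 1+1+1+1 = 4
    assert msdwa_param_count(cfg) == 12
    assert SEMSDWA(cfg).num_parameters() == 12


@given(c=st.integers(1, 96), r=st.integers(1, 16), dw=st.sampled_from([3, 5, 7]))
@settings(max_examples=20, deadline=None)
def test_msdwa_analytic_count_equals_enumeration(c, r, dw):
    cfg = MSDWAConfig(c, dw_kernel=dw, se=SEConfig(c, r))
    assert SEMSDWA(cfg).num_parameters() == msdwa_param_count(cfg)


def test_msdwa_count_strictly_increasing_in_channels():
    counts = [msdwa_param_count(MSDWAConfig(c, se=SEConfig(c, 4)))
              for c in range(4, 64, 4)]
    assert all(b > a for a, b in zip(counts, counts[1:]))


def test_depthwise_stage_has_no_cross_channel_mixing(rng):
    """Zeroing one input channel leaves other channels' branch outputs unchanged."""
    blk = SEMSDWA(MSDWAConfig(8, se=SEConfig(8, 2)))
    x = rng.normal(size=(1, 8, 10, 10)).astype(np.float32)
    x2 = x.copy()
    x2[:, 3] = 0.0

    def branch_stage(inp):
        d = blk.dw(nn.Tensor(inp))
        s = d
        for b in blk.branches:
            s = s + b(d)
        return s.data

    a, b = branch_stage(x), branch_stage(x2)
    others = [c for c in range(8) if c != 3]
    assert np.array_equal(a[:, others], b[:, others])
    assert not np.array_equal(a[:, 3], b[:, 3])


def test_msdwa_insertion_budget_near_printed_delta():
    """The backbone-end insertion (C=512) costs ~0.56 M parameters."""
    cfg = MSDWAConfig(512, se=SEConfig(512, 2))
    assert abs(msdwa_param_count(cfg) / 1e6 - 0.56) < 0.03


# ---------------------------------------------------------------------------
# multi-head self-attention / CGFM
# ---------------------------------------------------------------------------

def test_attention_rows_sum_to_one(rng):
    mh = MultiHeadSelfAttention(16, 4)
    x = nn.Tensor(rng.normal(size=(2, 16, 5, 5)).astype(np.float32))
    att = mh.attention_matrix(x)
    assert att.shape == (2, 4, 25, 25)
    assert np.abs(att.sum(axis=-1) - 1.0).max() < 1e-5


def test_attention_preserves_shape(rng):
    mh = MultiHeadSelfAttention(32, 4)
    x = nn.Tensor(rng.normal(size=(1, 32, 8, 8)).astype(np.float32))
    assert mh(x).data.shape == (1, 32, 8, 8)


def test_attention_single_token_is_value_projection(rng):
    mh = MultiHeadSelfAttention(8, 2)
    x = nn.Tensor(rng.normal(size=(1, 8, 1, 1)).astype(np.float32))
    att = mh.attention_matrix(x)
    assert np.allclose(att, 1.0)
    expected = mh.proj(mh.v(x)).data
    assert np.allclose(mh(x).data, expected, atol=1e-6)


def test_attention_rejects_indivisible_heads():
    with pytest.raises(ValueError):
        MultiHeadSelfAttention(10, 4)


def test_cgfm_channel_conservation(rng):
    cfg = CGFMConfig(128, 128, heads=4)
    blk = CGFM(cfg)
    x1 = nn.Tensor(rng.normal(size=(1, 128, 12, 12)).astype(np.float32))
    x2 = nn.Tensor(rng.normal(size=(1, 128, 12, 12)).astype(np.float32))
    out = blk(x1, x2)
    assert out.data.shape == (1, 256, 12, 12)


def test_cgfm_diagnostic_mode_degenerates_to_concat(rng):
    blk = CGFM(CGFMConfig(8, 4, heads=4))
    x1 = nn.Tensor(rng.normal(size=(2, 8, 6, 6)).astype(np.float32))
    x2 = nn.Tensor(rng.normal(size=(2, 4, 6, 6)).astype(np.float32))
    blk.diagnostic = True
    out = blk(x1, x2)
    assert np.array_equal(out.data, np.concatenate([x1.data, x2.data], axis=1))


def test_cgfm_gates_bounded(rng):
    blk = CGFM(CGFMConfig(8, 4, heads=4))
    x1 = nn.Tensor(rng.normal(size=(1, 8, 5, 5)).astype(np.float32))
    x2 = nn.Tensor(rng.normal(size=(1, 4, 5, 5)).astype(np.float32))
    z = blk.pre(nn.cat([x1, x2]))
    g = blk.attn(z).sigmoid().data
    assert np.all(g > 0) and np.all(g < 1)


def test_cgfm_spatial_mismatch_raises(rng):
    blk = CGFM(CGFMConfig(8, 8, heads=4))
    x1 = nn.Tensor(np.zeros((1, 8, 6, 6), np.float32))
    x2 = nn.Tensor(np.zeros((1, 8, 5, 5), np.float32))
    with pytest.raises(ValueError):
        blk(x1, x2)


@given(c1=st.sampled_from([4, 8, 16]), c2=st.sampled_from([4, 8, 16]),
       use_e=st.booleans())
@settings(max_examples=15, deadline=None)
def test_cgfm_analytic_count_equals_enumeration(c1, c2, use_e):
    e = (c1 + c2) // 2 if use_e else None
    if e is not None and e % 4:
        e = 4 * (e // 4)
    cfg = CGFMConfig(c1, c2, heads=4, attn_dim=e)
    assert CGFM(cfg).num_parameters() == cgfm_param_count(cfg)


def test_cgfm_total_neck_budget_near_printed_delta():
    """All four neck replacements together cost ~6.94 M parameters."""
    total = sum(cgfm_param_count(CGFMConfig(a, b, heads=4, attn_dim=e))
                for a, b, e in NECK_NODES_S)
    assert abs(total / 1e6 - 6.94) < 0.03


def test_cgfm_attention_downsampling_keeps_contracts(rng):
    """Maps above 20 px attend on strided tokens but output shape is unchanged."""
    blk = CGFM(CGFMConfig(8, 8, heads=4, sa_stride=2))
    x1 = nn.Tensor(rng.normal(size=(1, 8, 24, 24)).astype(np.float32))
    x2 = nn.Tensor(rng.normal(size=(1, 8, 24, 24)).astype(np.float32))
    assert blk(x1, x2).data.shape == (1, 16, 24, 24)
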