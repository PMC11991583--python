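"""Unit and property tests for the detector's building blocks."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lgwheatnet import engine as E
from lgwheatnet.blocks import (
    BNParams, BatchNorm2d, Conv2d, DWDown, DWDownConfig, SPPF, SPPFConfig,
    SeCUIB, SeCUIBConfig, SqueezeExcite, batch_norm, channel_shuffle,
    channel_shuffle_inverse, shuffle_permutation, silu,
)
from lgwheatnet.engine import Tensor


# ---------------------------------------------------------------------------
# silu
# ---------------------------------------------------------------------------

def test_silu_values():
    assert silu(0.0) == 0.0
    assert abs(silu(-30.0)) < 1e-8
    assert silu(1.0) == pytest.approx(0.731059, abs=1e-6)
    # tensor path agrees with scalar path
    x = np.linspace(-5, 5, 11)
    np.testing.assert_allclose(E.silu(Tensor(x)).data, silu(x), rtol=1e-6)


# ---------------------------------------------------------------------------
# channel shuffle
# ---------------------------------------------------------------------------

def test_channel_shuffle_explicit_permutation():
    x = np.arange(4, dtype=float).reshape(1, 4, 1, 1)
    y = channel_shuffle(x, 2)
    assert y.ravel().tolist() == [0.0, 2.0, 1.0, 3.0]


def test_channel_shuffle_identity_cases():
    x = np.random.default_rng(0).normal(size=(2, 4, 3, 3))
    np.testing.assert_array_equal(channel_shuffle(x, 1), x)
    np.testing.assert_array_equal(channel_shuffle(x, 4), x)


def test_channel_shuffle_rejects_bad_groups():
    with pytest.raises(ValueError):
        channel_shuffle(np.zeros((1, 6, 2, 2)), 4)


def test_channel_shuffle_inverse_exhaustive():
    """shuffle followed by its inverse is the identity for every divisor pair
    with C <= 32 (exhaustive index check)."""
    for c in range(1, 33):
        for g in range(1, c + 1):
            if c % g:
                continue
            x = np.arange(c, dtype=float).reshape(1, c, 1, 1)
            y = channel_shuffle_inverse(channel_shuffle(x, g), g)
            np.testing.assert_array_equal(y, x)
            # and the permutation is a true bijection
            assert sorted(shuffle_permutation(c, g).tolist()) == list(range(c))


def test_channel_shuffle_tensor_matches_numpy():
    x = np.random.default_rng(3).normal(size=(2, 8, 4, 5))
    np.testing.assert_allclose(channel_shuffle(Tensor(x), 4).data,
                               channel_shuffle(x, 4), rtol=1e-6)


# ---------------------------------------------------------------------------
# squeeze-excitation
# ---------------------------------------------------------------------------

def test_squeeze_excite_zero_weights_halves_input(rng):
    se = SqueezeExcite(8, 0.25)
    for p in se.parameters():
        p.data[...] = 0.0
    x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
    y = se(Tensor(x))
    np.testing.assert_allclose(y.data, 0.5 * x, rtol=1e-6)


def test_squeeze_excite_identity_gate_path():
    """Constant single-channel input c through a 1->1->1 identity gate path
    (unit weights, no bias) must scale the map by sigmoid(c)."""
    se = SqueezeExcite(1, 1.0)
    se.reduce.weight.data[...] = 1.0
    se.expand.weight.data[...] = 1.0
    se.reduce.bias.data[...] = 0.0
    se.expand.bias.data[...] = 0.0
    for c in (0.3, 1.7, 2.5):
        x = np.full((1, 1, 4, 4), c, dtype=np.float32)
        y = se(Tensor(x))
        expected = c / (1 + np.exp(-c)) * np.ones_like(x)
        np.testing.assert_allclose(y.data, expected, rtol=1e-5)


def test_squeeze_excite_preserves_shape(rng):
    for c, h, w in [(3, 2, 7), (16, 9, 4), (5, 1, 1)]:
        x = rng.normal(size=(2, c, h, w)).astype(np.float32)
        assert SqueezeExcite(c, 0.25)(Tensor(x)).shape == x.shape


# ---------------------------------------------------------------------------
# batch norm
# ---------------------------------------------------------------------------

def test_batch_norm_scalar_example():
    p = BNParams(mean=[1.0], var=[4.0], gamma=[3.0], beta=[1.0], eps=1e-12)
    out = batch_norm(np.full((1, 1, 1, 1), 2.0), p)
    assert out.item() == pytest.approx(2.5, abs=1e-6)


def test_batch_norm_identity_and_constant():
    eps = 1e-5
    x = np.random.default_rng(5).normal(size=(2, 3, 4, 4))
    ident = BNParams(mean=np.zeros(3), var=np.ones(3) - eps,
                     gamma=np.ones(3), beta=np.zeros(3), eps=eps)
    np.testing.assert_allclose(batch_norm(x, ident), x, rtol=1e-6)
    flat = BNParams(mean=np.zeros(3), var=np.ones(3), gamma=np.zeros(3),
                    beta=np.full(3, 7.0))
    np.testing.assert_allclose(batch_norm(x, flat), np.full_like(x, 7.0))


def test_batch_norm_rejects_invalid():
    with pytest.raises(ValueError):
        BNParams(mean=[0], var=[-1.0], gamma=[1], beta=[0])
    with pytest.raises(ValueError):
        BNParams(mean=[0], var=[1.0], gamma=[1], beta=[0], eps=0.0)


# ---------------------------------------------------------------------------
# SeCUIB
# ---------------------------------------------------------------------------

def _zero_residual_block(c=32):
    cfg = SeCUIBConfig(c, c, stride=1, start_dw_kernel=0, mid_dw_kernel=3,
                       hidden_channels=2 * c)
    blk = SeCUIB(cfg)
    for name, p in blk.named_parameters():
        if name.endswith("weight") or name.endswith("bias"):
            p.data[...] = 0.0
    return blk.eval()


def test_secuib_zero_weights_is_identity():
    """With zero conv weights and identity BN the projection path emits zero,
    so a residual-eligible block reduces to the identity map."""
    blk = _zero_residual_block()
    x = np.random.default_rng(7).normal(size=(2, 32, 8, 8)).astype(np.float32)
    with E.no_grad():
        y = blk(Tensor(x))
    np.testing.assert_allclose(y.data, x, atol=1e-6)


def test_secuib_stride2_halves_resolution():
    cfg = SeCUIBConfig(8, 16, stride=2, start_dw_kernel=3, mid_dw_kernel=3,
                       hidden_channels=16)
    blk = SeCUIB(cfg).eval()
    with E.no_grad():
        y = blk(Tensor(np.zeros((1, 8, 64, 64), dtype=np.float32)))
    assert y.shape == (1, 16, 32, 32)


def test_secuib_invalid_configs():
    with pytest.raises(ValueError):
        SeCUIBConfig(8, 8, stride=2, start_dw_kernel=0, mid_dw_kernel=0)
    with pytest.raises(ValueError):
        SeCUIBConfig(8, 8, hidden_channels=15, shuffle_groups=2).hidden


def secuib_param_oracle(cfg: SeCUIBConfig, use_se: bool) -> int:
    """Independent layer-by-layer parameter sum for a (Se)CUIB block."""
    ci, co, h = cfg.in_channels, cfg.out_channels, cfg.hidden
    n = 0
    if cfg.start_dw_kernel:
        n += cfg.start_dw_kernel ** 2 * ci + 2 * ci
    n += ci * h + 2 * h
    if cfg.mid_dw_kernel:
        n += cfg.mid_dw_kernel ** 2 * h + 2 * h
    n += h * co + 2 * co
    if use_se:
        r = max(1, round(co * cfg.se_ratio))
        n += co * r + r + r * co + co
    return n


@settings(max_examples=25, deadline=None)
@given(st.integers(2, 24), st.integers(1, 24), st.integers(1, 6),
       st.sampled_from([0, 3, 5]), st.sampled_from([3, 5]),
       st.sampled_from([1, 2]), st.booleans())
def test_secuib_param_count_matches_oracle(ci, co, ratio, ks, km, stride, use_se):
    cfg = SeCUIBConfig(2 * ci, co, stride=stride, start_dw_kernel=ks,
                       mid_dw_kernel=km, hidden_channels=2 * ci * ratio)
    blk = SeCUIB(cfg, use_se=use_se, use_shuffle=use_se)
    assert blk.num_parameters() == secuib_param_oracle(cfg, use_se)


@settings(max_examples=15, deadline=None)
@given(st.integers(1, 3), st.integers(2, 10), st.integers(1, 12),
       st.sampled_from([1, 2]), st.integers(3, 12), st.integers(3, 12))
def test_secuib_shape_contract(n, ci, co, stride, h, w):
    """Any valid config maps (N, Cin, H, W) -> (N, Cout, ceil(H/s), ceil(W/s))."""
    cfg = SeCUIBConfig(2 * ci, co, stride=stride, start_dw_kernel=3,
                       mid_dw_kernel=3, hidden_channels=4 * ci)
    blk = SeCUIB(cfg).eval()
    with E.no_grad():
        y = blk(Tensor(np.zeros((n, 2 * ci, h, w), dtype=np.float32)))
    assert y.shape == (n, co, -(-h // stride), -(-w // stride))


# ---------------------------------------------------------------------------
# DWDown
# ---------------------------------------------------------------------------

def test_dwdown_shape_contract():
    blk = DWDown(DWDownConfig(64, 128)).eval()
    with E.no_grad():
        y = blk(Tensor(np.zeros((1, 64, 40, 40), dtype=np.float32)))
        z = blk(Tensor(np.zeros((1, 64, 41, 41), dtype=np.float32)))
    assert y.shape == (1, 128, 20, 20)
    assert z.shape == (1, 128, 21, 21)  # ceil division on odd dims


def test_dwdown_param_count():
    blk = DWDown(DWDownConfig(64, 128, dw_kernel=3))
    assert blk.num_parameters() == 64 * 128 + 9 * 128 + 2 * 128


def test_dwdown_rejects_stride_one():
    with pytest.raises(ValueError):
        DWDownConfig(8, 8, stride=1)


# ---------------------------------------------------------------------------
# SPPF
# ---------------------------------------------------------------------------

def test_sppf_shape_and_constant_input():
    blk = SPPF(SPPFConfig(256, 256)).eval()
    with E.no_grad():
        y = blk(Tensor(np.zeros((1, 256, 20, 20), dtype=np.float32)))
    assert y.shape == (1, 256, 20, 20)
    # constant input stays spatially constant (max of a constant is itself)
    x = np.ones((1, 256, 8, 8), dtype=np.float32) * 0.37
    with E.no_grad():
        y = blk(Tensor(x)).data
    np.testing.assert_allclose(y, np.broadcast_to(y[:, :, :1, :1], y.shape), atol=1e-5)


def test_sppf_receptive_fields_of_chained_pools():
    """Three chained 5x5 stride-1 max pools see 5, 9, 13 pixels: an impulse
    spreads to exactly that width after each pool."""
    x = np.zeros((1, 1, 1, 31), dtype=np.float32)
    x[0, 0, 0, 15] = 1.0
    t = Tensor(x)
    widths = []
    for _ in range(3):
        t = E.max_pool2d(t, 5)
        widths.append(int((t.data > 0).sum()))
    assert widths == [5, 9, 13]


def test_sppf_param_count():
    cfg = SPPFConfig(120, 120)
    h = 60
    assert SPPF(cfg).num_parameters() == 120 * h + 2 * h + 4 * h * 120 + 2 * 120
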