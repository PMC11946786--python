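"""Temporal feature fusion: grouping round trips, attention contracts, CA."""

import numpy as np
import pytest

from echomasa.nn import Tensor
from echomasa.tffm import (
    TCSAConfig,
    TFFM,
    fuse_temporal_channel,
    group_windows,
    ungroup_windows,
    unfuse_temporal_channel,
)


def small_tffm(T=2, C=2, H=4, W=4, r=1, D=4, windows=(1, 2, 4), seed=0):
    cfg = TCSAConfig(r=r, D=D, window_sizes=windows)
    return TFFM(T, C, H, W, cfg, rng=np.random.default_rng(seed))


# -- fuse / group round trips -------------------------------------------------


def test_fuse_shapes_and_roundtrip(rng):
    clip = rng.normal(size=(8, 3, 16, 16)).astype(np.float32)
    fused = fuse_temporal_channel(clip)
    assert fused.shape == (24, 16, 16)
    assert np.array_equal(unfuse_temporal_channel(fused, 8), clip)
    one = rng.normal(size=(1, 5, 4, 4)).astype(np.float32)
    assert np.array_equal(fuse_temporal_channel(one), one[0])


def test_group_windows_partition_arithmetic(rng):
    block = rng.normal(size=(64, 10))
    g = group_windows(block, 4)
    assert g.shape == (16, 4, 10)
    assert np.array_equal(ungroup_windows(g), block)
    whole = group_windows(block, 64)
    assert whole.shape == (1, 64, 10)
    with pytest.raises(ValueError):
        group_windows(block, 5)


def test_tcsa_config_validation():
    with pytest.raises(ValueError):
        TCSAConfig(r=2, D=16, window_sizes=(2, 4))       # not three windows
    with pytest.raises(ValueError):
        TCSAConfig(r=2, D=16, window_sizes=(2, 4, 7))    # 7 does not divide 64
    with pytest.raises(ValueError):
        TFFM(2, 1, 5, 5, TCSAConfig(r=2, D=4, window_sizes=(1, 2, 4)))  # r | H fails


# -- embedding ----------------------------------------------------------------


def test_embed_compress_shapes(rng):
    m = small_tffm(T=8, C=3, H=112, W=112, r=2, D=16, windows=(2, 4, 8))
    fused = Tensor(rng.normal(size=(1, 24, 112, 112)).astype(np.float32))
    assert m.embed_compress_qkv(fused).shape == (1, 192, 56, 56)
    m1 = small_tffm(T=2, C=2, H=4, W=4, r=1, D=4)
    fused1 = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
    assert m1.embed_compress_qkv(fused1).shape == (1, 12, 4, 4)


def test_embed_zero_input_zero_output(rng):
    m = small_tffm()
    out = m.embed_compress_qkv(Tensor(np.zeros((1, 4, 4, 4), np.float32)))
    assert np.allclose(out.data, 0.0)


# -- TCSA ---------------------------------------------------------------------


def test_tcsa_preserves_shape(rng):
    for T in (1, 4, 8):
        m = small_tffm(T=T, C=2, H=8, W=8, r=2, D=4, windows=(2, 4, 8))
        clip = Tensor(rng.normal(size=(2, T, 2, 8, 8)).astype(np.float32))
        assert m.tcsa(clip).shape == clip.shape
        assert m(clip).shape == clip.shape


def test_tcsa_uniform_attention_single_group(rng):
    """Q = K = 0 makes attention uniform: each output slot in a group is the
    mean of the group's V rows (checked through the restoration conv)."""
    m = small_tffm(T=2, C=2, H=4, W=4, r=1, D=4, windows=(4, 4, 4))
    # zero the Q and K thirds of the embedding so scores vanish
    block = m.block
    m.embed.weight.data[: 2 * block] = 0.0
    m.embed.bias.data[: 2 * block] = 0.0
    clip = Tensor(rng.normal(size=(1, 2, 2, 4, 4)).astype(np.float32))
    emb = m.embed_compress_qkv(clip.reshape(1, 4, 4, 4)).data
    v = emb[0, 2 * block:].reshape(block, -1)
    mean_v = np.broadcast_to(v.reshape(1, 4, -1).mean(axis=1, keepdims=True),
                             (1, 4, v.shape[-1])).reshape(block, -1)
    got = m.tcsa(clip)
    # expected: identity skip plus the three (identical-window) restorations
    expect = clip.data.reshape(1, 4, 4, 4).copy()
    for restore in m.restore:
        expect = expect + restore(
            Tensor(mean_v.reshape(1, block, 4, 4).astype(np.float32))
        ).data
    assert np.allclose(got.data.reshape(1, 4, 4, 4), expect, atol=1e-5)


def brute_tcsa(m, clip):
    """Straight-line loop reference for the TCSA stage."""
    B, T, C, H, W = clip.shape
    r, block = m.cfg.r, m.block
    out = clip.reshape(B, T * C, H, W).copy()
    for b in range(B):
        fused = clip[b].reshape(1, T * C, H, W)
        emb = m.embed_compress_qkv(Tensor(fused)).data[0]
        S = (H // r) * (W // r)
        flat = emb.reshape(3 * block, S)
        q, k, v = flat[:block], flat[block:2 * block], flat[2 * block:]
        for w, restore in zip(m.cfg.window_sizes, m.restore):
            res = np.zeros((block, S), dtype=np.float32)
            for g in range(block // w):
                qg = q[g * w:(g + 1) * w]
                kg = k[g * w:(g + 1) * w]
                vg = v[g * w:(g + 1) * w]
                scores = qg @ kg.T
                e = np.exp(scores - scores.max(axis=-1, keepdims=True))
                attn = e / e.sum(axis=-1, keepdims=True)
                res[g * w:(g + 1) * w] = attn @ vg
            restored = restore(Tensor(res.reshape(1, block, H // r, W // r)))
            out[b] += restored.data[0]
    return out.reshape(B, T, C, H, W)


def test_tcsa_matches_loop_reference(rng):
    m = small_tffm(T=2, C=2, H=4, W=4, r=1, D=4, windows=(1, 2, 4))
    clip = rng.normal(size=(2, 2, 2, 4, 4)).astype(np.float32)
    got = m.tcsa(Tensor(clip)).data
    ref = brute_tcsa(m, clip)
    assert np.abs(got - ref).max() < 1e-5


def test_tcsa_attention_rows_sum_to_one(rng):
    """Every attention row in every group is a probability distribution."""
    from echomasa.nn import functional as F

    m = small_tffm(T=2, C=1, H=4, W=4, r=2, D=8, windows=(2, 4, 8))
    clip = Tensor(rng.normal(size=(1, 2, 1, 4, 4)).astype(np.float32))
    emb = m.embed_compress_qkv(clip.reshape(1, 2, 4, 4))
    block = m.block
    flat = emb.reshape(1, 3 * block, 4)
    q, k = flat[:, :block], flat[:, block:2 * block]
    for w in m.cfg.window_sizes:
        G = block // w
        qg = q.reshape(1, G, w, 4)
        kg = k.reshape(1, G, w, 4)
        A = F.softmax(qg @ kg.transpose(0, 1, 3, 2), axis=-1)
        assert np.allclose(A.data.sum(axis=-1), 1.0, atol=1e-6)


def test_tcsa_window_size_one_is_value_passthrough(rng):
    """A single window of size 1 gives A = [1]: attention returns V exactly."""
    m = small_tffm(T=1, C=1, H=2, W=2, r=1, D=1, windows=(1, 1, 1))
    clip = rng.normal(size=(1, 1, 1, 2, 2)).astype(np.float32)
    emb = m.embed_compress_qkv(Tensor(clip.reshape(1, 1, 2, 2))).data
    v = emb[:, 2 * m.block:]
    expect = clip.reshape(1, 1, 2, 2).copy()
    for restore in m.restore:
        expect = expect + restore(Tensor(v)).data
    got = m.tcsa(Tensor(clip)).data.reshape(1, 1, 2, 2)
    assert np.allclose(got, expect.reshape(1, 1, 2, 2), atol=1e-6)


# -- channel aggregation ------------------------------------------------------


def test_channel_aggregate_s_zero_collapse(rng):
    """With s = 0 the aggregation residual collapses: CA(Y) == Y exactly,
    so the output is Conv1x1(Y) + X."""
    m = small_tffm(T=2, C=2, H=4, W=4)
    m.ca_s.data[:] = 0.0
    x = rng.normal(size=(1, 2, 2, 4, 4)).astype(np.float32)
    fused = Tensor(x.reshape(1, 4, 4, 4))
    y = m.ca_dw(m.ca_expand(m.ca_norm(fused))).gelu()
    expect = (m.ca_out(y).data + x.reshape(1, 4, 4, 4)).reshape(x.shape)
    got = m.channel_aggregate(Tensor(x)).data
    assert np.array_equal(got, expect)


def test_channel_aggregate_zero_input_zero_biases(rng):
    m = small_tffm()
    for p in m.parameters():
        p.data[:] = 0.0
    x = np.zeros((1, 2, 2, 4, 4), np.float32)
    assert np.allclose(m.channel_aggregate(Tensor(x)).data, 0.0)


def test_channel_aggregate_scalar_walkthrough():
    """1-frame 2-channel 2×2 input with hand-set unit kernels and s = 1,
    evaluated against an explicit scalar computation of the CA equations."""
    m = small_tffm(T=1, C=2, H=2, W=2, r=1, D=2, windows=(1, 1, 2), seed=3)
    ch, ech = 2, 4  # fused channels, expanded channels
    # identity-like setup: expansion duplicates channels, dwconv = center tap
    m.ca_norm.gamma.data[:] = 1.0
    m.ca_norm.beta.data[:] = 0.0
    m.ca_expand.weight.data[:] = 0.0
    for i in range(ech):
        m.ca_expand.weight.data[i, i % ch, 0, 0] = 1.0
    m.ca_expand.bias.data[:] = 0.0
    m.ca_dw.weight.data[:] = 0.0
    m.ca_dw.weight.data[:, 0, 1, 1] = 1.0  # 3×3 depthwise center tap
    m.ca_dw.bias.data[:] = 0.0
    m.ca_universal.weight.data[:] = 1.0
    m.ca_universal.bias.data[:] = 0.0
    m.ca_s.data[:] = 1.0
    m.ca_out.weight.data[:] = 0.0
    for i in range(ch):
        m.ca_out.weight.data[i, i, 0, 0] = 1.0
        m.ca_out.weight.data[i, i + ch, 0, 0] = 1.0
    m.ca_out.bias.data[:] = 0.0

    x = np.array([[[[1.0, 2.0], [3.0, 4.0]],
                   [[0.0, 1.0], [1.0, 0.0]]]], np.float32)[None]  # (1,1,2,2,2)

    def gelu(v):
        from scipy.special import erf
        return v * 0.5 * (1 + erf(v / np.sqrt(2)))

    # scalar walkthrough of the three CA equations
    fused = x.reshape(2, 2, 2)
    mu = fused.mean(axis=0)
    var = fused.var(axis=0)
    normed = (fused - mu) / np.sqrt(var + 1e-5)
    y = gelu(np.concatenate([normed, normed], axis=0))      # expand + center tap
    xu = gelu(y.sum(axis=0, keepdims=True))                 # universal feature
    ca = y + 1.0 * (y - xu)
    expect = (ca[:2] + ca[2:] + fused).reshape(1, 1, 2, 2, 2)

    got = m.channel_aggregate(Tensor(x)).data
    assert np.allclose(got, expect, atol=1e-5)


# -- full module --------------------------------------------------------------


def test_tffm_forward_shape_and_determinism(rng):
    for T in (1, 4, 8):
        m = small_tffm(T=T, C=1, H=8, W=8, r=2, D=4, windows=(2, 4, 8))
        clip = Tensor(rng.normal(size=(1, T, 1, 8, 8)).astype(np.float32))
        a = m(clip).data
        b = m(clip).data
        assert a.shape == clip.shape
        assert np.array_equal(a, b)


def test_key_frame_extraction_bounds(rng):
    m = small_tffm(T=4, C=1, H=4, W=4, r=2, D=2, windows=(1, 2, 4))
    clip = Tensor(rng.normal(size=(1, 4, 1, 4, 4)).astype(np.float32))
    out = m(clip)
    key = m.key_frame(out, 2)
    assert key.shape == (1, 1, 4, 4)
    assert np.array_equal(key.data, out.data[:, 2])
    with pytest.raises(IndexError):
        m.key_frame(out, 4)


def test_gradient_flows_to_all_frames(rng):
    """A loss on the enhanced key frame alone back-propagates into every
    input frame: the fusion genuinely mixes temporal information."""
    T = 4
    m = small_tffm(T=T, C=1, H=4, W=4, r=2, D=4, windows=(1, 2, 4))
    clip = Tensor(rng.normal(size=(1, T, 1, 4, 4)).astype(np.float32),
                  requires_grad=True)
    key = m.key_frame(m(clip), 1)
    (key * key).sum().backward()
    norms = [float(np.abs(clip.grad[0, t]).sum()) for t in range(T)]
    assert all(n > 0 for n in norms)
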