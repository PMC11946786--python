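"""Neural-network primitives: convolutions, resampling, softmax, layer norm.

Convolutions use an im2col/col2im formulation so both directions reduce to
batched matrix products.  Bilinear resizing is expressed through two small
1D interpolation matrices (half-pixel-center convention), which makes its
adjoint exact.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


# -- im2col machinery ---------------------------------------------------------

def _conv_out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(B,C,H,W) -> (B, C*kh*kw, OH*OW) patch matrix."""
    B, C, H, W = x.shape
    OH = _conv_out_size(H, kh, stride, pad)
    OW = _conv_out_size(W, kw, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (B, C, kh, kw, OH, OW), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return win.reshape(B, C * kh * kw, OH * OW), OH, OW


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Adjoint of ``_im2col`` (overlap-add)."""
    B, C, H, W = x_shape
    OH = _conv_out_size(H, kh, stride, pad)
    OW = _conv_out_size(W, kw, stride, pad)
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    c6 = cols.reshape(B, C, kh, kw, OH, OW)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride] += c6[
                :, :, i, j
            ]
    return xp[:, :, pad : pad + H, pad : pad + W]


# -- convolution --------------------------------------------------------------

def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2D convolution, weight (Cout, Cin//groups, kh, kw)."""
    B, C, H, W = x.shape
    Cout, Cin_g, kh, kw = weight.shape
    if C != Cin_g * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {C} channels, "
            f"weight expects {Cin_g * groups} ({groups} groups)"
        )
    cols, OH, OW = _im2col(x.data, kh, kw, stride, padding)
    L = OH * OW
    cols_g = cols.reshape(B, groups, Cin_g * kh * kw, L)
    w_g = weight.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
    out = np.matmul(w_g[None], cols_g).reshape(B, Cout, OH, OW)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        go = g.reshape(B, groups, Cout // groups, L)
        if weight.requires_grad:
            gw = np.einsum("bgol,bgkl->gok", go, cols_g, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(np.swapaxes(w_g, -1, -2)[None], go)
            gx = _col2im(
                gcols.reshape(B, C * kh * kw, L), x.data.shape, kh, kw, stride, padding
            )
            x._accum(gx)

    return Tensor._make(out, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1) -> Tensor:
    """Transposed convolution (no padding), weight (Cin, Cout, kh, kw).

    With kernel == stride this is the exact inverse-shape map of the
    space-to-channel embedding used by the temporal fusion module.
    """
    B, Cin, H, W = x.shape
    Cin_w, Cout, kh, kw = weight.shape
    if Cin != Cin_w:
        raise ValueError(f"conv_transpose2d: {Cin} input channels vs weight {Cin_w}")
    OH = (H - 1) * stride + kh
    OW = (W - 1) * stride + kw
    w2 = weight.data.reshape(Cin, Cout * kh * kw)
    cols = np.matmul(w2.T[None], x.data.reshape(B, Cin, H * W))
    out = _col2im(cols, (B, Cout, OH, OW), kh, kw, stride, 0)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gcols, _, _ = _im2col(g[:, :, : OH, : OW], kh, kw, stride, 0)
        if x.requires_grad:
            gx = np.matmul(w2[None], gcols).reshape(B, Cin, H, W)
            x._accum(gx)
        if weight.requires_grad:
            gw = np.einsum("bil,bkl->ik", x.data.reshape(B, Cin, H * W), gcols, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, backward)


# -- resampling ---------------------------------------------------------------

def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1D bilinear interpolation matrix, half-pixel centers (align_corners=False)."""
    M = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (src - i0).astype(np.float32)
    M[np.arange(n_out), i0] += 1.0 - w1
    M[np.arange(n_out), i1] += w1
    return M


def interpolate_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Resize (B,C,H,W) to (B,C,OH,OW) by separable bilinear interpolation."""
    B, C, H, W = x.shape
    OH, OW = size
    if (OH, OW) == (H, W):
        return x
    R = _interp_matrix(OH, H)
    Cm = _interp_matrix(OW, W)
    out = np.einsum("oh,bchw,pw->bcop", R, x.data, Cm, optimize=True)

    def backward(g):
        gx = np.einsum("oh,bcop,pw->bchw", R, g, Cm, optimize=True)
        x._accum(gx)

    return Tensor._make(out, (x,), backward)


# -- normalizations and activations -------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (row-max subtracted as a constant)."""
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, axis: int, eps: float = 1e-5) -> Tensor:
    """Normalize over one axis; gamma/beta broadcast along it."""
    mu = x.mean(axis=axis, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=axis, keepdims=True)
    y = xc * ((var + eps) ** -0.5)
    return y * gamma + beta
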