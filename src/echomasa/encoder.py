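"""Four-stage Vision RetNet feature extractor.

Each stage stacks identical layers of: conditional positional encoding
(depth-wise 3×3, residual), Manhattan self-attention, local context
enhancement (depth-wise 5×5 on the value path), and a feed-forward network.
Stages 1–3 use the decomposed (axial) form of MaSA and never materialize the
N×N Manhattan decay matrix; stage 4 uses the full form on the coarsest grid.
A convolutional stem enters at stride 4 (two stride-2 3×3 convolutions, the
default) or stride 2 (single convolution), and a stride-2 3×3 convolution
precedes each later stage, so the pyramid strides are {4, 8, 16, 32}.

The differentiable attention here mirrors :mod:`echomasa.attention` exactly
(tested for agreement); it only adds batching and multiple heads with the
per-head decay schedule ``gamma_h = 1 - 2**(-5 - h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import decay_2d, decay_axis, default_head_gammas
from .nn import Tensor
from .nn import functional as F

__all__ = ["StageConfig", "RetNetLayer", "VisionRetNet", "masa_full_t", "masa_decomposed_t"]


# decay matrices depend only on (grid size, gamma); cache them across layers
_DECAY_CACHE: dict[tuple, Tensor] = {}


def _decay_tensor(kind: str, dims: tuple[int, ...], gammas: np.ndarray) -> Tensor:
    key = (kind, dims, gammas.tobytes())
    if key not in _DECAY_CACHE:
        if kind == "manhattan_2d":
            H, W = dims
            D = np.stack([decay_2d(H, W, g) for g in gammas])
        else:  # "axial": symmetric 1D decay along one grid axis
            (n,) = dims
            D = np.stack([decay_axis(n, g) for g in gammas])
        _DECAY_CACHE[key] = Tensor(D)
    return _DECAY_CACHE[key]


def _split_heads(x: Tensor, heads: int) -> Tensor:
    """(B, C, H, W) -> (B, heads, H, W, dh)"""
    B, C, H, W = x.shape
    return x.reshape(B, heads, C // heads, H, W).transpose(0, 1, 3, 4, 2)


def _merge_heads(x: Tensor) -> Tensor:
    """(B, heads, H, W, dh) -> (B, C, H, W)"""
    B, h, H, W, dh = x.shape
    return x.transpose(0, 1, 4, 2, 3).reshape(B, h * dh, H, W)


def masa_full_t(q: Tensor, k: Tensor, v: Tensor, heads: int, gammas: np.ndarray) -> Tensor:
    """Differentiable full MaSA on (B, C, H, W) maps; row-major token order."""
    B, C, H, W = q.shape
    N = H * W
    qh = _split_heads(q, heads).reshape(B, heads, N, C // heads)
    kh = _split_heads(k, heads).reshape(B, heads, N, C // heads)
    vh = _split_heads(v, heads).reshape(B, heads, N, C // heads)
    scores = qh @ kh.transpose(0, 1, 3, 2)
    D = _decay_tensor("manhattan_2d", (H, W), gammas)  # (heads, N, N)
    A = F.softmax(scores, axis=-1) * D.reshape(1, heads, N, N)
    out = (A @ vh).reshape(B, heads, H, W, C // heads)
    return _merge_heads(out)


def masa_decomposed_t(q: Tensor, k: Tensor, v: Tensor, heads: int, gammas: np.ndarray) -> Tensor:
    """Differentiable decomposed MaSA: height-axis attention then width-axis."""
    B, C, H, W = q.shape
    qh, kh, vh = (_split_heads(t, heads) for t in (q, k, v))  # (B, h, H, W, dh)

    # height axis: one attention per column
    qc = qh.transpose(0, 1, 3, 2, 4)  # (B, h, W, H, dh)
    kc = kh.transpose(0, 1, 3, 2, 4)
    vc = vh.transpose(0, 1, 3, 2, 4)
    Dv = _decay_tensor("axial", (H,), gammas)
    Av = F.softmax(qc @ kc.transpose(0, 1, 2, 4, 3), axis=-1) * Dv.reshape(1, heads, 1, H, H)
    u = (Av @ vc).transpose(0, 1, 3, 2, 4)  # back to (B, h, H, W, dh)

    # width axis: one attention per row
    Dw = _decay_tensor("axial", (W,), gammas)
    Ah = F.softmax(qh @ kh.transpose(0, 1, 2, 4, 3), axis=-1) * Dw.reshape(1, heads, 1, W, W)
    return _merge_heads(Ah @ u)


@dataclass
class StageConfig:
    """Architecture of the four-stage encoder.

    Defaults follow the backbone lineage this encoder descends from; all
    fields are configurable.  ``use_decomposed`` must keep stage 4 on the
    full form and stages 1-3 on the decomposed form to match the intended
    stage policy, but other patterns are accepted for experimentation.
    """

    depths: tuple[int, ...] = (3, 4, 18, 4)
    widths: tuple[int, ...] = (64, 128, 256, 512)
    heads: tuple[int, ...] = (4, 4, 8, 16)
    use_decomposed: tuple[bool, ...] = (True, True, True, False)
    ffn_ratio: int = 4
    stem_double: bool = True  # stride-4 entry (two stride-2 convs); False -> stride 2
    in_channels: int = 3

    def __post_init__(self):
        for name in ("depths", "widths", "heads", "use_decomposed"):
            if len(getattr(self, name)) != 4:
                raise ValueError(f"{name} must have exactly 4 entries")
        if any(d < 1 for d in self.depths):
            raise ValueError("stage depths must be positive")
        if any(w2 < w1 for w1, w2 in zip(self.widths, self.widths[1:])):
            raise ValueError("stage widths must be non-decreasing")
        for w, h in zip(self.widths, self.heads):
            if w % h:
                raise ValueError(f"width {w} not divisible by {h} heads")


class RetNetLayer(nn.Module):
    def __init__(self, channels: int, heads: int, decomposed: bool, ffn_ratio: int,
                 rng: np.random.Generator, gammas: np.ndarray | None = None):
        self.heads = heads
        self.decomposed = decomposed
        self.gammas = default_head_gammas(heads) if gammas is None else np.asarray(gammas)
        self.cpe = nn.DepthwiseConv2d(channels, 3, rng=rng)
        self.norm1 = nn.ChannelLayerNorm(channels)
        self.q_proj = nn.Conv2d(channels, channels, 1, rng=rng)
        self.k_proj = nn.Conv2d(channels, channels, 1, rng=rng)
        self.v_proj = nn.Conv2d(channels, channels, 1, rng=rng)
        self.lce = nn.DepthwiseConv2d(channels, 5, rng=rng)
        self.out_proj = nn.Conv2d(channels, channels, 1, rng=rng)
        self.norm2 = nn.ChannelLayerNorm(channels)
        self.ffn1 = nn.Conv2d(channels, channels * ffn_ratio, 1, rng=rng)
        self.ffn2 = nn.Conv2d(channels * ffn_ratio, channels, 1, rng=rng)
        self.last_decay_kind: str | None = None  # introspection for the stage policy

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.cpe(x)
        y = self.norm1(x)
        q, k, v = self.q_proj(y), self.k_proj(y), self.v_proj(y)
        if self.decomposed:
            attn = masa_decomposed_t(q, k, v, self.heads, self.gammas)
            self.last_decay_kind = "axial"
        else:
            attn = masa_full_t(q, k, v, self.heads, self.gammas)
            self.last_decay_kind = "manhattan_2d"
        x = x + self.out_proj(attn + self.lce(v))
        return x + self.ffn2(self.ffn1(self.norm2(x)).gelu())


class Downsample(nn.Module):
    """3×3 stride-2 convolution; floor arithmetic, width transition."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(in_ch, out_ch, 3, stride=2, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] < 2 or x.shape[-2] < 2:
            raise ValueError(f"cannot downsample a {x.shape[-2]}×{x.shape[-1]} map")
        return self.conv(x)


class VisionRetNet(nn.Module):
    """The encoder: stem + 4 stages, returning a 4-level feature pyramid."""

    MIN_INPUT = 32

    def __init__(self, config: StageConfig | None = None, rng: np.random.Generator | None = None):
        self.config = config or StageConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        c = self.config
        if c.stem_double:
            self.stem = nn.Sequential(
                nn.Conv2d(c.in_channels, c.widths[0], 3, stride=2, padding=1, rng=rng),
                _Gelu(),
                nn.Conv2d(c.widths[0], c.widths[0], 3, stride=2, padding=1, rng=rng),
            )
        else:
            self.stem = nn.Conv2d(c.in_channels, c.widths[0], 3, stride=2, padding=1, rng=rng)
        self.downsamples = [
            Downsample(c.widths[i], c.widths[i + 1], rng) for i in range(3)
        ]
        self.stages = []
        for i in range(4):
            self.stages.append([
                RetNetLayer(c.widths[i], c.heads[i], c.use_decomposed[i], c.ffn_ratio, rng)
                for _ in range(c.depths[i])
            ])

    def forward(self, x: Tensor) -> list[Tensor]:
        return self.encode(x)

    def encode(self, x: Tensor) -> list[Tensor]:
        """Image (B, C, H, W) -> four feature maps at strides {4, 8, 16, 32}."""
        B, C, H, W = x.shape
        if H < self.MIN_INPUT or W < self.MIN_INPUT:
            raise ValueError(
                f"input {H}×{W} too small: the encoder needs at least "
                f"{self.MIN_INPUT} px on each side"
            )
        x = self.stem(x)
        pyramid = []
        for i in range(4):
            if i > 0:
                x = self.downsamples[i - 1](x)
            for layer in self.stages[i]:
                x = layer(x)
            pyramid.append(x)
        return pyramid

    def decay_usage(self) -> dict[int, set[str]]:
        """Which decay-matrix kinds each stage used in the last forward pass."""
        return {
            i: {l.last_decay_kind for l in stage if l.last_decay_kind is not None}
            for i, stage in enumerate(self.stages)
        }


class _Gelu(nn.Module):
    def forward(self, x):
        return x.gelu()
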