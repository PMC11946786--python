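"""Temporal Feature Fusion Module (TFFM).

A clip of T frames is fused along the channel axis (T·C channels), embedded
into a compressed spatial grid whose channels carry query/key/value blocks,
and self-attention is computed over the fused temporal–channel axis inside
non-overlapping windows of three different lengths.  The three restored
outputs are summed (temporal–channel self-attention, TCSA), and a channel
aggregation (CA) stage then injects complementary inter-frame features:
a "universal" single-channel feature is extracted with a 1×1 convolution
and its deviation from each channel, scaled by a learnable per-channel
parameter ``s``, refines the representation.

Window grouping uses non-overlapping windows (stride = window size) so the
group/restore round trip is an exact partition inverse.  Q, K and V occupy
the first, middle and last thirds of the embedded 3·r²·D channel axis.
The TCSA stage carries an identity skip from the fused clip to the summed
restorations: the enhanced clip is the input plus learned temporal context,
so the key frame's intensity signal survives random initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F

__all__ = [
    "TCSAConfig",
    "TFFM",
    "fuse_temporal_channel",
    "unfuse_temporal_channel",
    "group_windows",
    "ungroup_windows",
]


@dataclass
class TCSAConfig:
    """Temporal–channel self-attention hyperparameters.

    r is the spatial compression ratio (r divides H and W), D the embedded
    dimension per compressed cell, and window_sizes the three temporal–
    channel window lengths (each must divide r²·D).
    """

    r: int = 2
    D: int = 16
    window_sizes: tuple[int, int, int] = (2, 4, 8)

    def __post_init__(self):
        if len(self.window_sizes) != 3:
            raise ValueError("exactly three window sizes are required")
        block = self.r * self.r * self.D
        for w in self.window_sizes:
            if w < 1 or block % w:
                raise ValueError(f"window size {w} must divide r²·D = {block}")


def fuse_temporal_channel(clip: np.ndarray) -> np.ndarray:
    """(T, C, H, W) -> (T·C, H, W): frames concatenated along channels."""
    T, C, H, W = clip.shape
    return clip.reshape(T * C, H, W)


def unfuse_temporal_channel(fused: np.ndarray, T: int) -> np.ndarray:
    TC, H, W = fused.shape
    return fused.reshape(T, TC // T, H, W)


def group_windows(block: np.ndarray, w: int) -> np.ndarray:
    """Partition (M, S) into (M // w, w, S) contiguous windows (stride = w)."""
    M, S = block.shape
    if M % w:
        raise ValueError(f"window size {w} does not divide the fused axis ({M})")
    return block.reshape(M // w, w, S)


def ungroup_windows(groups: np.ndarray) -> np.ndarray:
    G, w, S = groups.shape
    return groups.reshape(G * w, S)


class TFFM(nn.Module):
    """TCSA followed by channel aggregation; shape-preserving on clips."""

    def __init__(self, T: int, C: int, H: int, W: int, config: TCSAConfig | None = None,
                 ca_expansion: int = 2, rng: np.random.Generator | None = None):
        cfg = config or TCSAConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        if H % cfg.r or W % cfg.r:
            raise ValueError(f"r={cfg.r} must divide the frame size {H}×{W}")
        self.cfg = cfg
        self.T, self.C, self.H, self.W = T, C, H, W
        block = cfg.r * cfg.r * cfg.D
        self.block = block
        # space-to-channel embedding producing the Q|K|V stack
        self.embed = nn.Conv2d(T * C, 3 * block, cfg.r, stride=cfg.r, rng=rng)
        # per-window-size restoration back to (T·C, H, W)
        self.restore = [
            nn.ConvTranspose2d(block, T * C, cfg.r, stride=cfg.r, rng=rng)
            for _ in cfg.window_sizes
        ]
        # channel aggregation
        ch = T * C
        self.ca_norm = nn.ChannelLayerNorm(ch)
        self.ca_expand = nn.Conv2d(ch, ca_expansion * ch, 1, rng=rng)
        self.ca_dw = nn.DepthwiseConv2d(ca_expansion * ch, 3, rng=rng)
        self.ca_universal = nn.Conv2d(ca_expansion * ch, 1, 1, rng=rng)
        self.ca_s = nn.Parameter(np.zeros((1, ca_expansion * ch, 1, 1), dtype=np.float32))
        self.ca_out = nn.Conv2d(ca_expansion * ch, ch, 1, rng=rng)

    # -- TCSA -----------------------------------------------------------------

    def embed_compress_qkv(self, fused: Tensor) -> Tensor:
        """(B, T·C, H, W) -> (B, 3·r²·D, H/r, W/r); Q, K, V thirds in order."""
        return self.embed(fused)

    def tcsa(self, clip: Tensor) -> Tensor:
        """Temporal–channel self-attention over a (B, T, C, H, W) clip."""
        B, T, C, H, W = clip.shape
        fused = clip.reshape(B, T * C, H, W)
        emb = self.embed_compress_qkv(fused)
        r, block = self.cfg.r, self.block
        S = (H // r) * (W // r)
        flat = emb.reshape(B, 3 * block, S)
        q, k, v = flat[:, :block], flat[:, block : 2 * block], flat[:, 2 * block :]
        out = fused  # identity skip: keeps the clip's signal at initialization
        for w, restore in zip(self.cfg.window_sizes, self.restore):
            G = block // w
            qg = q.reshape(B, G, w, S)
            kg = k.reshape(B, G, w, S)
            vg = v.reshape(B, G, w, S)
            A = F.softmax(qg @ kg.transpose(0, 1, 3, 2), axis=-1)  # (B, G, w, w)
            out = out + restore((A @ vg).reshape(B, block, H // r, W // r))
        return out.reshape(B, T, C, H, W)

    # -- channel aggregation --------------------------------------------------

    def channel_aggregate(self, x: Tensor) -> Tensor:
        """CA stage on a (B, T, C, H, W) clip; shape preserved."""
        B, T, C, H, W = x.shape
        fused = x.reshape(B, T * C, H, W)
        y = self.ca_dw(self.ca_expand(self.ca_norm(fused))).gelu()
        universal = self.ca_universal(y).gelu()  # (B, 1, H, W), broadcast-subtracted
        ca = y + self.ca_s * (y - universal)
        out = self.ca_out(ca) + fused
        return out.reshape(B, T, C, H, W)

    # -- full module ----------------------------------------------------------

    def forward(self, clip: Tensor) -> Tensor:
        return self.channel_aggregate(self.tcsa(clip))

    def key_frame(self, enhanced: Tensor, key_index: int) -> Tensor:
        """Extract the enhanced key frame: (B, T, C, H, W) -> (B, C, H, W)."""
        if not (0 <= key_index < enhanced.shape[1]):
            raise IndexError(f"key index {key_index} outside clip of length {enhanced.shape[1]}")
        return enhanced[:, key_index]
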