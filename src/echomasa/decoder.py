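"""Feature-pyramid decoder and segmentation head.

Each of the four encoder levels is projected to a common width with a 1×1
convolution, bilinearly upsampled to the finest level's resolution, and the
four maps are summed element-wise.  The head (3×3 conv + GELU + 1×1 conv)
produces single-channel logits, bilinearly upsampled to the input frame
resolution; probabilities are ``sigmoid(logits)``, masks threshold at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F

__all__ = ["DecoderConfig", "FPNDecoder"]


@dataclass
class DecoderConfig:
    fpn_width: int = 64
    num_classes: int = 1  # binary left-ventricle mask
    # initial value of the head's output bias.  Starting the mask map at a
    # positive prior (rather than 0) keeps the background's descent coupled
    # to the features from the first step, which L1 training on heavily
    # imbalanced masks needs: the all-background map is the pixelwise-median
    # optimum and a cold start can stall there.
    head_bias_init: float = 0.2

    def __post_init__(self):
        if self.fpn_width < 1:
            raise ValueError("fpn_width must be >= 1")


class FPNDecoder(nn.Module):
    def __init__(self, in_widths, config: DecoderConfig | None = None,
                 rng: np.random.Generator | None = None):
        if len(in_widths) != 4:
            raise ValueError(f"expected a 4-level pyramid, got {len(in_widths)} widths")
        cfg = config or DecoderConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.proj = [nn.Conv2d(w, cfg.fpn_width, 1, rng=rng) for w in in_widths]
        # normalizing the fused map keeps logit magnitudes bounded by the head
        # weights, which MAE-on-probability training needs to stay responsive
        self.fuse_norm = nn.ChannelLayerNorm(cfg.fpn_width)
        self.head_conv = nn.Conv2d(cfg.fpn_width, cfg.fpn_width, 3, padding=1, rng=rng)
        # centering the pre-activation keeps the head's GELU responsive even
        # when early training drives the whole map toward the background class
        self.head_norm = nn.ChannelLayerNorm(cfg.fpn_width)
        # random weights + positive prior bias: see DecoderConfig.head_bias_init
        self.head_out = nn.Conv2d(cfg.fpn_width, cfg.num_classes, 1, rng=rng)
        self.head_out.bias.data[:] = cfg.head_bias_init

    def fpn_decode(self, pyramid: list[Tensor]) -> Tensor:
        """Project, upsample to the finest level, and sum the four levels."""
        if len(pyramid) != 4:
            raise ValueError(f"expected 4 pyramid levels, got {len(pyramid)}")
        target = pyramid[0].shape[-2:]
        fused = None
        for level, proj in zip(pyramid, self.proj):
            x = F.interpolate_bilinear(proj(level), target)
            fused = x if fused is None else fused + x
        return fused

    def seg_head(self, fused: Tensor, out_size: tuple[int, int]) -> Tensor:
        """Fused map -> logits at the input frame resolution."""
        logits = self.head_out(self.head_norm(self.head_conv(self.fuse_norm(fused))).gelu())
        return F.interpolate_bilinear(logits, out_size)

    def forward(self, pyramid: list[Tensor], out_size: tuple[int, int]) -> Tensor:
        return self.seg_head(self.fpn_decode(pyramid), out_size)
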