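"""Model assembly: TFFM -> key-frame extraction -> encoder -> FPN decoder."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .decoder import DecoderConfig, FPNDecoder
from .encoder import StageConfig, VisionRetNet
from .nn import Tensor
from .tffm import TCSAConfig, TFFM

__all__ = ["ModelConfig", "EchoSegModel", "assemble_model"]


@dataclass
class ModelConfig:
    """Everything needed to rebuild the segmentation model."""

    frames: int = 8
    channels: int = 3
    image_size: int = 112
    key_index: int = 4  # clips are laid out as 4 frames before the key + key + 3 after
    # "sigmoid": probability map = sigmoid(head output); "linear": the head
    # output itself is the (L1-regressed) mask map, clipped to [0, 1].  The
    # MAE training criterion applies to this map either way; the linear head
    # keeps gradients alive at small data scales where the sigmoid saturates.
    head: str = "sigmoid"
    tcsa: TCSAConfig = field(default_factory=TCSAConfig)
    ca_expansion: int = 2
    encoder: StageConfig = field(default_factory=StageConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)

    def __post_init__(self):
        if not (0 <= self.key_index < self.frames):
            raise ValueError("key_index must lie inside the clip")
        if self.head not in ("sigmoid", "linear"):
            raise ValueError("head must be 'sigmoid' or 'linear'")
        if self.encoder.in_channels != self.channels:
            self.encoder = dataclasses.replace(self.encoder, in_channels=self.channels)

    @classmethod
    def reduced(cls, image_size: int = 64, channels: int = 1) -> "ModelConfig":
        """A small configuration for quick experiments and sanity runs."""
        return cls(
            channels=channels,
            image_size=image_size,
            head="linear",
            tcsa=TCSAConfig(r=2, D=8, window_sizes=(2, 4, 8)),
            encoder=StageConfig(
                depths=(1, 1, 2, 1),
                widths=(16, 32, 64, 128),
                heads=(2, 2, 4, 8),
                in_channels=channels,
            ),
            decoder=DecoderConfig(fpn_width=32),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tcsa"]["window_sizes"] = list(d["tcsa"]["window_sizes"])
        for k in ("depths", "widths", "heads", "use_decomposed"):
            d["encoder"][k] = list(d["encoder"][k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "tcsa" in d:
            t = dict(d["tcsa"])
            t["window_sizes"] = tuple(t["window_sizes"])
            d["tcsa"] = TCSAConfig(**t)
        if "encoder" in d:
            e = dict(d["encoder"])
            for k in ("depths", "widths", "heads", "use_decomposed"):
                if k in e:
                    e[k] = tuple(e[k])
            d["encoder"] = StageConfig(**e)
        if "decoder" in d:
            d["decoder"] = DecoderConfig(**d["decoder"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class EchoSegModel(nn.Module):
    """End-to-end clip -> key-frame logits segmentation model."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        cfg = config
        if cfg.image_size < VisionRetNet.MIN_INPUT:
            raise ValueError(f"image_size must be >= {VisionRetNet.MIN_INPUT}")
        self.config = cfg
        self.tffm = TFFM(cfg.frames, cfg.channels, cfg.image_size, cfg.image_size,
                         cfg.tcsa, cfg.ca_expansion, rng=rng)
        self.encoder = VisionRetNet(cfg.encoder, rng=rng)
        self.decoder = FPNDecoder(cfg.encoder.widths, cfg.decoder, rng=rng)

    def forward(self, clip: Tensor) -> Tensor:
        """(B, T, C, H, W) clip -> (B, 1, H, W) key-frame logits."""
        B, T, C, H, W = clip.shape
        if (T, C, H, W) != (self.config.frames, self.config.channels,
                            self.config.image_size, self.config.image_size):
            raise ValueError(
                f"clip shape {clip.shape[1:]} does not match the model configuration "
                f"({self.config.frames}, {self.config.channels}, "
                f"{self.config.image_size}, {self.config.image_size})"
            )
        enhanced = self.tffm(clip)
        key = self.tffm.key_frame(enhanced, self.config.key_index)
        pyramid = self.encoder.encode(key)
        return self.decoder(pyramid, (H, W))

    def proba_map(self, out: Tensor) -> Tensor:
        """Head output -> probability-like mask map (differentiable)."""
        return out.sigmoid() if self.config.head == "sigmoid" else out

    def predict_proba(self, clip: np.ndarray) -> np.ndarray:
        """(T, C, H, W) or (B, T, C, H, W) clip -> key-frame probabilities."""
        from scipy.special import expit

        arr = np.asarray(clip, dtype=np.float32)
        squeeze = arr.ndim == 4
        if squeeze:
            arr = arr[None]
        with nn.no_grad():
            out = self.forward(Tensor(arr)).data[:, 0]
        proba = expit(out) if self.config.head == "sigmoid" else np.clip(out, 0.0, 1.0)
        return proba[0] if squeeze else proba

    def predict(self, clip: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Binary key-frame mask(s) at the given probability threshold."""
        return self.predict_proba(clip) >= threshold


def assemble_model(config: ModelConfig | None = None, seed: int = 0) -> EchoSegModel:
    """Build the full model with deterministic, seeded initialization."""
    return EchoSegModel(config or ModelConfig(), rng=np.random.default_rng(seed))
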