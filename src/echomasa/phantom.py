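"""Synthetic echocardiography phantom clips with ground-truth masks.

The generator emulates the phenomenology that makes left-ventricle
segmentation in ultrasound hard: a dark, pulsating elliptical lumen inside a
brighter myocardial rim, multiplicative speckle, low contrast, a sector-
shaped field of view, and occasional truncation of the ventricle at the
sector edge.  It is not a wave-propagation simulator — speckle is modelled
as unit-mean multiplicative noise (a gamma law, the squared-magnitude
Rayleigh family) whose standard deviation is the configured strength.

Cardiac phase runs over a full cycle: the ellipse axes scale smoothly with
``s(t) = 1 - (1 - sqrt(f)) * (1 - cos 2πt) / 2`` so the cross-sectional area
is maximal at end-diastole (phase 0), minimal at end-systole (phase 0.5),
and the ES/ED area ratio equals the configured systolic area fraction ``f``.
Clips are framed so the ED and ES key frames both admit the 4-before /
3-after clip window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage.draw import ellipse as _sk_ellipse

from .data import (
    CLIP_AFTER,
    CLIP_BEFORE,
    EchoRecord,
    KeyFrame,
    trace_from_mask,
    write_echonet_style,
)

__all__ = ["PhantomConfig", "phantom_frame", "generate_clip", "generate_corpus", "speckle_field"]


@dataclass
class PhantomConfig:
    image_size: int = 112
    frames: int = 16                      # one full cardiac cycle per clip
    center_frac: tuple[float, float] = (0.52, 0.5)   # (row, col) of the LV center
    center_jitter: float = 0.04           # uniform jitter of the center, fraction of size
    axes_frac: tuple[float, float] = (0.24, 0.16)    # ED semi-axes, fraction of size
    axes_jitter: float = 0.15             # relative jitter of the semi-axes
    rotation_range: float = 0.35          # ellipse tilt, radians
    systolic_area_fraction: float = 0.5   # ES area / ED area
    lumen_intensity: float = 0.12
    contrast: float = 1.0                 # scales rim/background against the lumen
    speckle_strength: float = 0.5         # std of the unit-mean multiplicative noise
    blur_sigma: float = 1.0
    sector_angle_deg: float = 75.0
    out_of_view_prob: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.systolic_area_fraction < 1.0):
            raise ValueError("systolic area fraction must lie in (0, 1)")
        if self.speckle_strength < 0:
            raise ValueError("speckle strength must be >= 0")
        if not (0.0 < self.sector_angle_deg <= 180.0):
            raise ValueError("sector angle must lie in (0, 180] degrees")

    @property
    def ed_index(self) -> int:
        return CLIP_BEFORE  # phase 0 lands here by construction

    @property
    def es_index(self) -> int:
        return CLIP_BEFORE + self.frames // 2

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {
                "center_frac": list(self.center_frac), "axes_frac": list(self.axes_frac)
            }, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("center_frac", "axes_frac"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def speckle_field(shape, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative speckle (gamma law, std = strength)."""
    if strength <= 0:
        return np.ones(shape, dtype=np.float32)
    k = 1.0 / (strength * strength)
    return rng.gamma(k, 1.0 / k, size=shape).astype(np.float32)


def _phase_scale(t: float, area_fraction: float) -> float:
    return 1.0 - (1.0 - np.sqrt(area_fraction)) * (1.0 - np.cos(2.0 * np.pi * t)) / 2.0


def _sector_mask(n: int, angle_deg: float, apex: tuple[float, float]) -> np.ndarray:
    rows, cols = np.mgrid[0:n, 0:n]
    dr = rows - apex[0]
    dc = cols - apex[1]
    half = np.deg2rad(angle_deg) / 2.0
    ang = np.arctan2(np.abs(dc), dr)  # 0 = straight down from the apex
    dist = np.hypot(dr, dc)
    return (dr >= 0) & (ang <= half) & (dist <= 0.95 * n)


@dataclass
class _ClipGeometry:
    center: tuple[float, float]
    axes: tuple[float, float]
    rotation: float
    apex: tuple[float, float]


def _draw_geometry(config: PhantomConfig, rng: np.random.Generator) -> _ClipGeometry:
    n = config.image_size
    jit = config.center_jitter * n
    center = (config.center_frac[0] * n + rng.uniform(-jit, jit),
              config.center_frac[1] * n + rng.uniform(-jit, jit))
    axes = tuple(
        a * n * (1.0 + rng.uniform(-config.axes_jitter, config.axes_jitter))
        for a in config.axes_frac
    )
    rotation = rng.uniform(-config.rotation_range, config.rotation_range)
    apex = [2.0, n / 2.0]
    if rng.random() < config.out_of_view_prob:
        # shift the sector apex sideways so one ventricle edge exits the sector
        apex[1] += rng.choice([-1.0, 1.0]) * 0.25 * n
    if max(axes) * 1.4 > n / 2:
        raise ValueError("ellipse larger than the image")
    return _ClipGeometry(center, axes, rotation, tuple(apex))


def _render_frame(config: PhantomConfig, geom: _ClipGeometry, t: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = config.image_size
    s = _phase_scale(t, config.systolic_area_fraction)
    sector = _sector_mask(n, config.sector_angle_deg, geom.apex)

    lumen = np.zeros((n, n), dtype=bool)
    rr, cc = _sk_ellipse(*geom.center, s * geom.axes[0], s * geom.axes[1],
                         shape=(n, n), rotation=geom.rotation)
    lumen[rr, cc] = True
    rim = np.zeros((n, n), dtype=bool)
    rr, cc = _sk_ellipse(*geom.center, s * geom.axes[0] * 1.35 + 2, s * geom.axes[1] * 1.35 + 2,
                         shape=(n, n), rotation=geom.rotation)
    rim[rr, cc] = True

    c = config.contrast
    img = np.full((n, n), config.lumen_intensity + 0.22 * c, dtype=np.float32)
    img[rim] = config.lumen_intensity + 0.5 * c
    img[lumen] = config.lumen_intensity
    img *= speckle_field(img.shape, config.speckle_strength, rng)
    if config.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, config.blur_sigma)
    img = np.where(sector, img, 0.0)
    mask = lumen & sector
    return np.clip(img, 0.0, 1.0).astype(np.float32), mask


def phantom_frame(config: PhantomConfig, t: float,
                  rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame at cycle phase ``t`` in [0, 1): (image, LV mask)."""
    if not (0.0 <= t < 1.0):
        raise ValueError("cycle phase must lie in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    geom = _draw_geometry(config, rng)
    return _render_frame(config, geom, t, rng)


def generate_clip(config: PhantomConfig, seed: int) -> EchoRecord:
    """One clip spanning a full cardiac cycle, masks attached at ED and ES.

    Frame ``i`` is rendered at phase ``(i - ed_index) / frames mod 1``, so
    ED (maximal area) falls at index 4 and ES (minimal area) half a cycle
    later — both admit the 4-before / 3-after clip window.
    """
    if config.frames < 8 or config.es_index + CLIP_AFTER >= config.frames:
        raise ValueError(
            f"frames={config.frames} violates the 8-frame clip window around the "
            f"ED ({config.ed_index}) / ES ({config.es_index}) key frames"
        )
    rng = np.random.default_rng(seed)
    geom = _draw_geometry(config, rng)
    frames = np.empty((config.frames, config.image_size, config.image_size), dtype=np.uint8)
    masks = {}
    for i in range(config.frames):
        t = ((i - config.ed_index) / config.frames) % 1.0
        img, mask = _render_frame(config, geom, t, rng)
        frames[i] = np.round(img * 255.0).astype(np.uint8)
        if i in (config.ed_index, config.es_index):
            masks[i] = mask
    rec = EchoRecord(f"phantom{seed:06d}", frames)
    for idx, ftype in ((config.ed_index, "ED"), (config.es_index, "ES")):
        mask = masks[idx]
        rec.key_frames.append(KeyFrame(idx, ftype, mask=mask, trace=trace_from_mask(mask)))
    return rec


def split_sizes(n: int) -> tuple[int, int, int]:
    """70/15/15 split; train and val round down, the remainder is test."""
    n_train = int(np.floor(0.7 * n))
    n_val = int(np.floor(0.15 * n))
    return n_train, n_val, n - n_train - n_val


def generate_corpus(n: int, config: PhantomConfig, out_dir=None, seed: int | None = None):
    """Generate ``n`` phantom clips with train/val/test splits.

    Per-clip seeds derive from ``(seed, index)`` so clip ``i`` is identical
    across regenerations.  If ``out_dir`` is given the corpus is also
    written in the EchoNet-style dialect.
    Returns ``(records, splits)``.
    """
    if n < 3:
        raise ValueError("a corpus needs at least 3 clips (one per split)")
    base = config.seed if seed is None else seed
    mix = np.random.SeedSequence(base)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in mix.spawn(n)]
    records = [generate_clip(config, s) for s in child_seeds]
    n_train, n_val, n_test = split_sizes(n)
    splits = ["TRAIN"] * n_train + ["VAL"] * n_val + ["TEST"] * n_test
    if out_dir is not None:
        write_echonet_style(records, splits, out_dir)
    return records, splits
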