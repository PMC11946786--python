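"""Segmentation metrics: Dice similarity and (95th-percentile) Hausdorff distance.

Conventions
-----------
* dice: ``2|A∩B| / (|A|+|B|)``; two empty masks agree perfectly (1.0), an
  empty prediction against a non-empty reference scores 0.0.
* Hausdorff distances are computed between the masks' inner boundaries
  (pixels of the mask with at least one 8-neighbour outside it), in pixel
  units with 0-based (row, col) coordinates.
* ``hd95`` takes the 95th percentile of each directed distance distribution
  (the common medical-imaging convention) and then the max over the two
  directions, so ``hd95 <= hausdorff`` always.
* If either mask is empty the Hausdorff distances return the image diagonal
  as a sentinel (the worst geometrically meaningful value).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

__all__ = ["dice", "hausdorff", "hd95", "boundary_points", "SegReport", "evaluate_model"]


def _as_bool(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"masks must be 2D, got shape {m.shape}")
    return m.astype(bool)


def _check_pair(A, B):
    A, B = _as_bool(A), _as_bool(B)
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    return A, B


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks."""
    A, B = _check_pair(A, B)
    sa, sb = int(A.sum()), int(B.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(A, B).sum()) / (sa + sb)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Inner 8-connectivity boundary of a mask as (n, 2) pixel coordinates."""
    m = _as_bool(mask)
    eroded = ndimage.binary_erosion(m, structure=np.ones((3, 3), bool), border_value=0)
    return np.argwhere(m & ~eroded)


def _directed_distances(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """min-distance from each point of P to the set Q."""
    return cdist(P, Q).min(axis=1)


def _hd_core(A, B, reducer) -> float:
    A, B = _check_pair(A, B)
    if not A.any() or not B.any():
        return float(np.hypot(*A.shape))  # sentinel: image diagonal
    pa, pb = boundary_points(A), boundary_points(B)
    d_ab = _directed_distances(pa, pb)
    d_ba = _directed_distances(pb, pa)
    return float(max(reducer(d_ab), reducer(d_ba)))


def hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in pixels."""
    return _hd_core(A, B, np.max)


def hd95(A: np.ndarray, B: np.ndarray) -> float:
    """95th-percentile Hausdorff distance (outlier-robust boundary error)."""
    return _hd_core(A, B, lambda d: np.percentile(d, 95))


@dataclass
class SegReport:
    """Per-key-frame and aggregate segmentation results."""

    clip_ids: list[str] = field(default_factory=list)
    frame_types: list[str] = field(default_factory=list)  # "ED" / "ES"
    dsc: list[float] = field(default_factory=list)
    hd95: list[float] = field(default_factory=list)

    def add(self, clip_id: str, frame_type: str, dsc_value: float, hd95_value: float):
        self.clip_ids.append(clip_id)
        self.frame_types.append(frame_type)
        self.dsc.append(float(dsc_value))
        self.hd95.append(float(hd95_value))

    @property
    def mean_dsc(self) -> float:
        return float(np.mean(self.dsc))

    @property
    def mean_hd95(self) -> float:
        return float(np.mean(self.hd95))

    def counts_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.frame_types:
            out[t] = out.get(t, 0) + 1
        return out

    def by_type(self) -> dict[str, dict[str, float]]:
        out = {}
        for t in sorted(set(self.frame_types)):
            idx = [i for i, ft in enumerate(self.frame_types) if ft == t]
            out[t] = {
                "mean_dsc": float(np.mean([self.dsc[i] for i in idx])),
                "mean_hd95": float(np.mean([self.hd95[i] for i in idx])),
                "n": len(idx),
            }
        return out

    def to_json(self, path) -> None:
        payload = {
            "items": [
                {"clip_id": c, "frame_type": t, "dsc": d, "hd95": h}
                for c, t, d, h in zip(self.clip_ids, self.frame_types, self.dsc, self.hd95)
            ],
            "mean_dsc": self.mean_dsc,
            "mean_hd95": self.mean_hd95,
            "by_type": self.by_type(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "clip_id": self.clip_ids,
                "frame_type": self.frame_types,
                "dsc": self.dsc,
                "hd95": self.hd95,
            }
        ).to_csv(path, index=False)


def evaluate_model(model, items, threshold: float = 0.5) -> SegReport:
    """Evaluate a model over (clip_id, frame_type, clip, mask) items.

    ``model`` must expose ``predict(clip, threshold)`` returning a binary
    key-frame mask; items may be any iterable, e.g. from
    :func:`echomasa.data.clip_items`.
    """
    report = SegReport()
    n = 0
    for clip_id, frame_type, clip, mask in items:
        pred = model.predict(clip, threshold)
        report.add(clip_id, frame_type, dice(pred, mask), hd95(pred, mask))
        n += 1
    if n == 0:
        raise ValueError("evaluate_model: empty dataset")
    return report
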