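"""Dataset structures, readers, cleaning, clip sampling and augmentation.

Two on-disk dialects are supported:

* **EchoNet-style** — one grayscale video per file plus a tracings table of
  paired boundary coordinates per annotated frame, and a file list with
  train/val/test splits.  Videos are stored as multi-page TIFF (lossless,
  dependency-light); the CSV schema matches the EchoNet-Dynamic tables
  (``FileList.csv`` with FileName/NumberOfFrames/Split and
  ``VolumeTracings.csv`` with FileName/X1/Y1/X2/Y2/Frame, X = column,
  Y = row).
* **CAMUS-style** — per-patient image and labelled-mask volumes (MetaImage
  ``.mhd``/``.raw``) per view, with ED/ES frame indices in a small config
  file; only the endocardium label is retained as the left ventricle.

Pixel convention everywhere: 0-based (row, col) integer coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "KeyFrame",
    "EchoRecord",
    "CLIP_BEFORE",
    "CLIP_AFTER",
    "CLIP_LENGTH",
    "clean_dataset",
    "sample_clip",
    "clip_items",
    "rasterize_trace",
    "AugmentParams",
    "augment",
    "apply_augment",
    "write_echonet_style",
    "read_echonet_style",
    "write_camus_style",
    "read_camus_style",
]

# clip layout: 4 frames before the key frame, the key frame, 3 frames after
CLIP_BEFORE = 4
CLIP_AFTER = 3
CLIP_LENGTH = CLIP_BEFORE + 1 + CLIP_AFTER


@dataclass
class KeyFrame:
    index: int
    type: str  # "ED" or "ES"
    mask: np.ndarray | None = None   # (H, W) bool
    trace: np.ndarray | None = None  # (n, 4) paired (r1, c1, r2, c2) boundary points


@dataclass
class EchoRecord:
    """One echo video with its annotated key frames."""

    video_id: str
    frames: np.ndarray  # (F, H, W) uint8 grayscale
    key_frames: list[KeyFrame] = field(default_factory=list)

    @property
    def num_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


# -- cleaning and clip sampling ----------------------------------------------

def _window_fits(record: EchoRecord, key_index: int) -> bool:
    return key_index - CLIP_BEFORE >= 0 and key_index + CLIP_AFTER < record.num_frames


def clean_dataset(records: list[EchoRecord]) -> list[EchoRecord]:
    """Keep only records where every key frame admits the full 8-frame window."""
    return [r for r in records if r.key_frames
            and all(_window_fits(r, kf.index) for kf in r.key_frames)]


def sample_clip(record: EchoRecord, key_frame_index: int, channels: int = 1) -> tuple[np.ndarray, int]:
    """Extract the 8-frame clip [k-4, k+3] around a key frame.

    Returns ``(clip, key_index)`` with clip shaped (T, channels, H, W),
    float32 in [0, 1], grayscale replicated across channels; the key frame
    sits at position 4 within the clip.
    """
    if not _window_fits(record, key_frame_index):
        raise ValueError(
            f"key frame {key_frame_index} of video {record.video_id!r} lacks the "
            f"{CLIP_BEFORE} preceding / {CLIP_AFTER} following frames "
            f"(video has {record.num_frames})"
        )
    window = record.frames[key_frame_index - CLIP_BEFORE : key_frame_index + CLIP_AFTER + 1]
    clip = window.astype(np.float32) / 255.0
    clip = np.repeat(clip[:, None], channels, axis=1)
    return clip, CLIP_BEFORE


def clip_items(records: list[EchoRecord], channels: int = 1):
    """Yield (clip_id, frame_type, clip, mask) for every annotated key frame."""
    for r in records:
        for kf in r.key_frames:
            mask = kf.mask
            if mask is None and kf.trace is not None:
                mask = rasterize_trace(kf.trace, *r.frame_shape)
            clip, _ = sample_clip(r, kf.index, channels)
            yield f"{r.video_id}:{kf.index}", kf.type, clip, mask


# -- tracing rasterization ----------------------------------------------------

def rasterize_trace(trace: np.ndarray, H: int, W: int) -> np.ndarray:
    """Fill paired boundary coordinates into a binary mask.

    ``trace`` is (n, 4): each row holds one scanline's left and right
    boundary points as (r1, c1, r2, c2).  The polygon walks the left points
    top-to-bottom, then the right points bottom-to-top; it is filled with
    the even-odd pixel-center rule plus the polygon edge pixels, so an
    axis-aligned rectangle of k×m traced pixels yields exactly k·m set
    pixels.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 2 or trace.shape[1] != 4 or trace.shape[0] < 2:
        raise ValueError("rasterize_trace needs at least 2 coordinate pairs of (r1, c1, r2, c2)")
    rows = np.concatenate([trace[:, 0], trace[::-1, 2]])
    cols = np.concatenate([trace[:, 1], trace[::-1, 3]])
    if np.ptp(rows) == 0 or np.ptp(cols) == 0:
        raise ValueError("degenerate trace: boundary points are collinear")
    mask = np.zeros((H, W), dtype=bool)
    rr, cc = _sk_polygon(rows, cols, shape=(H, W))
    mask[rr, cc] = True
    # include the traced boundary pixels themselves
    ri = np.clip(np.round(rows).astype(int), 0, H - 1)
    ci = np.clip(np.round(cols).astype(int), 0, W - 1)
    mask[ri, ci] = True
    # close any 1-px gaps between interior fill and boundary points
    return ndimage.binary_fill_holes(mask)


# -- augmentation -------------------------------------------------------------

@dataclass
class AugmentParams:
    hflip: bool = False
    angle_deg: float = 0.0
    scale: float = 1.0
    shift_frac: tuple[float, float] = (0.0, 0.0)  # (row, col) as fraction of size
    brightness: float = 1.0
    contrast: float = 1.0

    @property
    def is_geometric_identity(self) -> bool:
        return (not self.hflip and self.angle_deg == 0.0 and self.scale == 1.0
                and self.shift_frac == (0.0, 0.0))

    @property
    def is_photometric_identity(self) -> bool:
        return self.brightness == 1.0 and self.contrast == 1.0


def draw_augment_params(rng: np.random.Generator) -> AugmentParams:
    """Sample one augmentation: flip, ±20° rotation, 0.9–1.1 scale,
    ±0.0625 shift, 0.8–1.2 brightness/contrast."""
    return AugmentParams(
        hflip=bool(rng.random() < 0.5),
        angle_deg=float(rng.uniform(-20.0, 20.0)),
        scale=float(rng.uniform(0.9, 1.1)),
        shift_frac=(float(rng.uniform(-0.0625, 0.0625)), float(rng.uniform(-0.0625, 0.0625))),
        brightness=float(rng.uniform(0.8, 1.2)),
        contrast=float(rng.uniform(0.8, 1.2)),
    )


def _affine_matrix(params: AugmentParams, H: int, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Output->input affine map (matrix, offset) about the image center."""
    theta = np.deg2rad(params.angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # forward transform: flip -> scale -> rotate -> shift; invert for resampling
    R = np.array([[c, -s], [s, c]])
    S = np.diag([params.scale, params.scale])
    Fm = np.diag([1.0, -1.0 if params.hflip else 1.0])
    A = R @ S @ Fm
    t = np.array([params.shift_frac[0] * H, params.shift_frac[1] * W])
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    Ainv = np.linalg.inv(A)
    offset = center - Ainv @ (center + t)
    return Ainv, offset


def apply_augment(clip: np.ndarray, mask: np.ndarray, params: AugmentParams):
    """Apply one sampled augmentation identically to all frames and the mask.

    Geometric transforms use bilinear resampling for frames and nearest-
    neighbour for the mask; photometric jitter touches the frames only.
    """
    clip = np.asarray(clip, dtype=np.float32)
    mask = np.asarray(mask)
    T, C, H, W = clip.shape
    out_clip = clip
    out_mask = mask.astype(bool)
    if not params.is_geometric_identity:
        Ainv, offset = _affine_matrix(params, H, W)
        out_clip = np.empty_like(clip)
        for t in range(T):
            for ch in range(C):
                out_clip[t, ch] = ndimage.affine_transform(
                    clip[t, ch], Ainv, offset=offset, order=1, mode="constant", cval=0.0
                )
        out_mask = ndimage.affine_transform(
            mask.astype(np.float32), Ainv, offset=offset, order=0, mode="constant", cval=0.0
        ).astype(bool)
    if not params.is_photometric_identity:
        mean = out_clip.mean(axis=(-2, -1), keepdims=True)
        out_clip = (out_clip - mean) * params.contrast + mean
        out_clip = np.clip(out_clip * params.brightness, 0.0, 1.0)
    elif out_clip is clip:
        out_clip = clip.copy()
    return out_clip, out_mask


def augment(clip: np.ndarray, mask: np.ndarray, seed: int):
    """Seeded augmentation of one (clip, mask) pair; deterministic per seed."""
    params = draw_augment_params(np.random.default_rng(seed))
    return apply_augment(clip, mask, params)


# -- EchoNet-style dialect -----------------------------------------------------

def write_echonet_style(records: list[EchoRecord], splits: list[str], out_dir) -> None:
    """Write records as <dir>/Videos/<id>.tif + FileList.csv + VolumeTracings.csv."""
    out = Path(out_dir)
    (out / "Videos").mkdir(parents=True, exist_ok=True)
    file_rows, trace_rows = [], []
    for rec, split in zip(records, splits):
        tifffile.imwrite(out / "Videos" / f"{rec.video_id}.tif", rec.frames)
        file_rows.append(
            {"FileName": rec.video_id, "NumberOfFrames": rec.num_frames, "Split": split}
        )
        for kf in rec.key_frames:
            trace = kf.trace
            if trace is None:
                if kf.mask is None:
                    continue
                trace = trace_from_mask(kf.mask)
            for r1, c1, r2, c2 in trace:
                trace_rows.append(
                    {"FileName": rec.video_id, "X1": c1, "Y1": r1, "X2": c2, "Y2": r2,
                     "Frame": kf.index}
                )
    pd.DataFrame(file_rows).to_csv(out / "FileList.csv", index=False)
    pd.DataFrame(trace_rows).to_csv(out / "VolumeTracings.csv", index=False)


def read_echonet_style(root, split: str | None = None, rasterize: bool = True) -> list[EchoRecord]:
    """Read an EchoNet-style corpus; key-frame types assigned by traced area
    (the larger of a video's two traced frames is ED)."""
    root = Path(root)
    files = pd.read_csv(root / "FileList.csv")
    traces = pd.read_csv(root / "VolumeTracings.csv")
    if split is not None:
        files = files[files["Split"].str.upper() == split.upper()]
    records = []
    for _, row in files.iterrows():
        vid = str(row["FileName"])
        frames = tifffile.imread(root / "Videos" / f"{vid}.tif")
        if frames.ndim == 2:
            frames = frames[None]
        H, W = frames.shape[1:]
        rec = EchoRecord(vid, frames)
        vid_traces = traces[traces["FileName"].astype(str) == vid]
        entries = []
        for frame_idx, grp in vid_traces.groupby("Frame"):
            trace = grp[["Y1", "X1", "Y2", "X2"]].to_numpy(dtype=np.float64)
            mask = rasterize_trace(trace, H, W) if rasterize else None
            area = int(mask.sum()) if mask is not None else float(
                np.ptp(grp["Y1"]) * np.ptp(np.maximum(grp["X2"], grp["X1"]))
            )
            entries.append((int(frame_idx), trace, mask, area))
        entries.sort(key=lambda e: -e[3])  # largest area first -> ED
        for rank, (frame_idx, trace, mask, _) in enumerate(entries):
            rec.key_frames.append(
                KeyFrame(frame_idx, "ED" if rank == 0 else "ES", mask=mask, trace=trace)
            )
        rec.key_frames.sort(key=lambda kf: kf.index)
        records.append(rec)
    return records


def trace_from_mask(mask: np.ndarray) -> np.ndarray:
    """Per-scanline paired boundary points (r, min_col, r, max_col) of a mask."""
    mask = np.asarray(mask).astype(bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size < 2:
        raise ValueError("mask too small to trace (fewer than 2 occupied rows)")
    out = np.empty((rows.size, 4), dtype=np.float64)
    for i, r in enumerate(rows):
        cols = np.flatnonzero(mask[r])
        out[i] = (r, cols[0], r, cols[-1])
    return out


# -- CAMUS-style dialect -------------------------------------------------------

def write_camus_style(records: list[EchoRecord], out_dir, view: str = "4CH",
                      lv_label: int = 1) -> None:
    """Write records as per-patient MetaImage volumes with ED/ES label masks."""
    import SimpleITK as sitk

    out = Path(out_dir)
    for rec in records:
        pdir = out / rec.video_id
        pdir.mkdir(parents=True, exist_ok=True)
        sitk.WriteImage(
            sitk.GetImageFromArray(rec.frames),
            str(pdir / f"{rec.video_id}_{view}_half_sequence.mhd"),
        )
        lines = [f"NbFrame: {rec.num_frames}"]
        for kf in rec.key_frames:
            gt = (kf.mask.astype(np.uint8) * lv_label)[None]
            sitk.WriteImage(
                sitk.GetImageFromArray(gt),
                str(pdir / f"{rec.video_id}_{view}_{kf.type}_gt.mhd"),
            )
            lines.append(f"{kf.type}: {kf.index}")
        (pdir / f"Info_{view}.cfg").write_text("\n".join(lines) + "\n")


def read_camus_style(root, view: str = "4CH", lv_label: int = 1) -> list[EchoRecord]:
    """Read a CAMUS-style corpus, retaining only the endocardium label."""
    import SimpleITK as sitk

    root = Path(root)
    records = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        pid = pdir.name
        seq_path = pdir / f"{pid}_{view}_half_sequence.mhd"
        info_path = pdir / f"Info_{view}.cfg"
        if not seq_path.exists():
            continue
        frames = sitk.GetArrayFromImage(sitk.ReadImage(str(seq_path)))
        info = {}
        if info_path.exists():
            for line in info_path.read_text().splitlines():
                if ":" in line:
                    k, v = line.split(":", 1)
                    info[k.strip()] = v.strip()
        rec = EchoRecord(pid, np.asarray(frames, dtype=np.uint8))
        for ftype in ("ED", "ES"):
            gt_path = pdir / f"{pid}_{view}_{ftype}_gt.mhd"
            if not gt_path.exists() or ftype not in info:
                continue
            gt = sitk.GetArrayFromImage(sitk.ReadImage(str(gt_path)))[0]
            rec.key_frames.append(KeyFrame(int(info[ftype]), ftype, mask=gt == lv_label))
        records.append(rec)
    return records
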