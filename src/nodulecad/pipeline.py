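"""End-to-end inference: preprocess, tile, detect, suppress, score.

A raw scan is preprocessed to a pre-image + lung mask, tiled with a
sliding window (default 240-voxel patches, stride 210, full coverage
with the last tile clamped to the volume edge), and each tile is run
through the detector.  Anchors with sigmoid probability >= the
candidate threshold (default 0.75) are decoded into boxes and shifted
into pre-image coordinates.  Pooled candidates then pass lung-mask
suppression and NMS (in that order by default), and — when a scorer is
supplied — CS-Net rescoring with the score threshold (default 0.05,
0 disables the second stage in effect).  Final candidates are reported
both in pre-image voxels and world millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anchors import build_anchor_grid, decode_offsets
from .core import Candidate, CTVolume, LungMask
from .fpr import score_and_filter
from .nn import sigmoid
from .preprocessing import FILL_GRAY, preprocess_scan
from .suppression import lms_filter, nms_iou

__all__ = ["InferenceConfig", "DetectionResult", "tile_volume",
           "detect_candidates", "detect_scan"]


@dataclass(frozen=True)
class InferenceConfig:
    patch_edge: int = 240
    stride: int = 210
    candidate_threshold: float = 0.75  # Cth on the detector probability
    score_threshold: float = 0.05      # Cs on the CS-Net score
    nms_iou: float = 0.001
    lms_cm: float = 0.8
    suppression_order: tuple[str, ...] = ("lms", "nms")
    resample_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: pre-suppression cap: keep at most this many anchors per tile,
    #: by probability (bounds memory/time when the threshold is permissive)
    max_per_tile: int = 2000

    def __post_init__(self):
        if self.stride > self.patch_edge:
            raise ValueError("stride must not exceed the patch edge")
        for t in (self.candidate_threshold, self.score_threshold):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must be in [0,1]")


@dataclass
class DetectionResult:
    scan_id: str
    candidates: list[Candidate]                       # pre-image voxels
    world_centers: list[tuple[float, float, float]]   # mm, (z,y,x)
    crop_offset: tuple[int, int, int]
    pre_image: CTVolume | None = None
    lung_mask: LungMask | None = None


def tile_volume(shape, patch_edge: int, stride: int) -> list[tuple[int, int, int]]:
    """Start coordinates of a covering set of cubic tiles."""
    if patch_edge < 1:
        raise ValueError("patch edge must be >= 1")
    starts_per_axis = []
    for s in shape:
        if s <= patch_edge:
            starts = [0]
        else:
            starts = list(range(0, s - patch_edge, stride)) + [s - patch_edge]
        starts_per_axis.append(starts)
    return [(z, y, x)
            for z in starts_per_axis[0]
            for y in starts_per_axis[1]
            for x in starts_per_axis[2]]


def _crop_tile(grid: np.ndarray, start, edge: int) -> np.ndarray:
    out = np.full((edge,) * 3, FILL_GRAY, dtype=grid.dtype)
    lo = np.asarray(start)
    hi = np.minimum(lo + edge, grid.shape)
    sl_src = tuple(slice(a, b) for a, b in zip(lo, hi))
    sl_dst = tuple(slice(0, b - a) for a, b in zip(lo, hi))
    out[sl_dst] = grid[sl_src]
    return out


def detect_candidates(pre_image: CTVolume, detector, cfg: InferenceConfig,
                      scan_id: str = "") -> list[Candidate]:
    """Run the detector over all tiles and decode raw candidates."""
    detector.eval()
    grid = np.asarray(pre_image.grid)
    edge = cfg.patch_edge
    anchor_grid = build_anchor_grid((edge,) * 3)
    out: list[Candidate] = []
    for start in tile_volume(grid.shape, edge, cfg.stride):
        tile = _crop_tile(grid, start, edge).astype(np.float32) / 255.0
        cls_logits, reg = detector(tile[None, None])
        probs = sigmoid(cls_logits.data.reshape(-1))
        keep = np.flatnonzero(probs >= cfg.candidate_threshold)
        if keep.size > cfg.max_per_tile:
            keep = keep[np.argsort(-probs[keep], kind="stable")
                        [: cfg.max_per_tile]]
        offsets = reg.data.reshape(-1, 4)
        for idx in keep:
            box = decode_offsets(offsets[idx], anchor_grid.boxes[idx])
            center = box[:3] + np.asarray(start, float)
            if np.any(center < 0) or np.any(center >= grid.shape):
                continue
            out.append(Candidate(center=tuple(center), diameter=float(box[3]),
                                 probability=float(probs[idx]),
                                 scan_id=scan_id))
    return out


def detect_scan(vol: CTVolume, detector, scorer=None,
                cfg: InferenceConfig = InferenceConfig(),
                scan_id: str = "") -> DetectionResult:
    """Full Algorithm-1 style inference on a raw scan."""
    pre, mask, crop_offset = preprocess_scan(vol, cfg.resample_spacing)
    candidates = detect_candidates(pre, detector, cfg, scan_id)
    for step in cfg.suppression_order:
        if step == "lms":
            candidates = lms_filter(candidates, mask, cfg.lms_cm)
        elif step == "nms":
            candidates = nms_iou(candidates, cfg.nms_iou)
        else:
            raise ValueError(f"unknown suppression step {step!r}")
    if scorer is not None:
        candidates = score_and_filter(candidates, pre, scorer,
                                      cfg.score_threshold)
    sp = np.asarray(cfg.resample_spacing)
    origin = np.asarray(vol.origin)
    world = [tuple(origin + (np.asarray(c.center) + np.asarray(crop_offset)) * sp)
             for c in candidates]
    return DetectionResult(scan_id=scan_id, candidates=candidates,
                           world_centers=world, crop_offset=tuple(crop_offset),
                           pre_image=pre, lung_mask=mask)
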