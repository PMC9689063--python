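"""Second-stage false-positive reduction: candidate patch extraction,
CS-Net scoring/thresholding, and the offline augmentation that builds
the scorer's training set.

Candidate patches are 1x32x32x32 gray crops of the pre-image centred on
the candidate; out-of-volume voxels are padded with gray 170 (the same
fill value preprocessing uses outside the lung mask).  Offline
augmentation turns each positive candidate into 40 patches via random
zoom in [0.8, 1.25], integer per-axis shifts in [-4, 4], and a random
flip/axis-transposition; negatives get a single unaugmented crop.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Candidate, CTVolume
from .preprocessing import FILL_GRAY

__all__ = [
    "CandidatePatch",
    "PATCH_SHAPE",
    "CS_THRESHOLD",
    "extract_candidate_patch",
    "score_candidates",
    "score_and_filter",
    "offline_augment",
    "save_patch_cache",
    "load_patch_cache",
]

PATCH_SHAPE = (32, 32, 32)
CS_THRESHOLD = 0.05

# the 48 signed axis permutations of a cube
_ORIENTATIONS = [(perm, flips)
                 for perm in permutations(range(3))
                 for flips in np.ndindex(2, 2, 2)]


@dataclass
class CandidatePatch:
    """A 1x32x32x32 gray patch with provenance and optional label."""

    grid: np.ndarray                 # (32,32,32) uint8 gray
    candidate: Candidate | None = None
    label: int | None = None         # 1 nodule, 0 non-nodule, None unknown

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.shape != PATCH_SHAPE:
            raise ValueError(f"candidate patch must be {PATCH_SHAPE}, "
                             f"got {self.grid.shape}")

    @property
    def tensor_input(self) -> np.ndarray:
        """(1,1,32,32,32) float32 in [0,1] for the scorer."""
        return (self.grid.astype(np.float32) / 255.0)[None, None]


def _crop_padded(grid: np.ndarray, center_vox, half: int,
                 fill=FILL_GRAY) -> np.ndarray:
    """Cube crop of edge 2*half centred on ``center_vox``, padded with fill."""
    c = np.round(np.asarray(center_vox, float)).astype(int)
    lo = c - half
    hi = c + half
    out = np.full((2 * half,) * 3, fill, dtype=grid.dtype)
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, grid.shape)
    if np.any(src_lo >= src_hi):
        return out
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
        grid[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    return out


def extract_candidate_patch(pre_image: CTVolume, candidate: Candidate
                            ) -> CandidatePatch:
    """32^3 crop of the pre-image centred on the candidate."""
    grid = np.asarray(pre_image.grid)
    c = np.asarray(candidate.center, float)
    if np.any(c < 0) or np.any(c >= grid.shape):
        raise ValueError(f"candidate center {tuple(c)} outside the pre-image")
    return CandidatePatch(grid=_crop_padded(grid, c, PATCH_SHAPE[0] // 2),
                          candidate=candidate)


def score_candidates(candidates: list[Candidate], pre_image: CTVolume,
                     model, chunk: int = 8) -> np.ndarray:
    """CS-Net scores for all candidates (order preserved).

    Scoring runs in small chunks: candidate lists can run to hundreds
    per scan and the network's working set scales with the batch.
    """
    if not candidates:
        return np.zeros(0)
    model.eval()
    out = []
    for start in range(0, len(candidates), chunk):
        batch = np.concatenate(
            [extract_candidate_patch(pre_image, c).tensor_input
             for c in candidates[start:start + chunk]])
        out.append(model(batch).data.reshape(-1))
    return np.concatenate(out)


def score_and_filter(candidates: list[Candidate], pre_image: CTVolume,
                     model, cs_threshold: float = CS_THRESHOLD
                     ) -> list[Candidate]:
    """Keep candidates whose CS-Net score is >= the threshold."""
    scores = score_candidates(candidates, pre_image, model)
    kept = []
    for c, s in zip(candidates, scores):
        c.score = float(s)
        if s >= cs_threshold:
            kept.append(c)
    return kept


def _augment_one(grid: np.ndarray, center, rng: np.random.Generator
                 ) -> np.ndarray:
    half = 32
    local = _crop_padded(grid, center, half).astype(np.float32)
    factor = rng.uniform(0.8, 1.25)
    zoomed = ndimage.zoom(local, factor, order=1, mode="nearest")
    mid = np.asarray(zoomed.shape) / 2.0
    shift = rng.integers(-4, 5, size=3)
    patch = _crop_padded(zoomed, mid + shift, PATCH_SHAPE[0] // 2)
    perm, flips = _ORIENTATIONS[rng.integers(len(_ORIENTATIONS))]
    patch = patch.transpose(perm)
    for ax, f in enumerate(flips):
        if f:
            patch = np.flip(patch, axis=ax)
    return np.clip(np.round(patch), 0, 255).astype(np.uint8)


def offline_augment(positives: list[Candidate], pre_images: dict[str, CTVolume],
                    rng: np.random.Generator, negatives: list[Candidate] = (),
                    reps: int = 40) -> list[CandidatePatch]:
    """Build the scorer training set: 40 augmented patches per positive,
    one plain crop per negative."""
    patches: list[CandidatePatch] = []
    for cand in positives:
        vol = pre_images[cand.scan_id]
        for _ in range(reps):
            grid = _augment_one(np.asarray(vol.grid), cand.center, rng)
            patches.append(CandidatePatch(grid=grid, candidate=cand, label=1))
    for cand in negatives:
        vol = pre_images[cand.scan_id]
        patch = extract_candidate_patch(vol, cand)
        patch.label = 0
        patches.append(patch)
    return patches


def save_patch_cache(patches: list[CandidatePatch], directory: str | Path) -> None:
    """Store a patch set on disk: one array container plus an index CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([p.grid for p in patches]) if patches else \
        np.zeros((0,) + PATCH_SHAPE, np.uint8)
    np.savez_compressed(directory / "patches.npz", patches=stack)
    index = pd.DataFrame(
        {
            "index": np.arange(len(patches)),
            "label": [p.label if p.label is not None else -1 for p in patches],
            "scan_id": [p.candidate.scan_id if p.candidate else "" for p in patches],
        }
    )
    index.to_csv(directory / "index.csv", index=False)


def load_patch_cache(directory: str | Path) -> list[CandidatePatch]:
    directory = Path(directory)
    with np.load(directory / "patches.npz") as data:
        stack = data["patches"]
    index = pd.read_csv(directory / "index.csv")
    out = []
    for i, row in index.iterrows():
        label = int(row["label"])
        out.append(CandidatePatch(grid=stack[i],
                                  label=None if label < 0 else label))
    return out
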