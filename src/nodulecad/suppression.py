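"""Candidate suppression: 3D NMS and lung-mask suppression (LMS).

NMS iterates candidates in descending detector probability and discards
any remaining candidate whose box IoU with a kept one exceeds the
threshold (default 0.001 — any material overlap suppresses).

LMS treats the lung mask as a density field: for a candidate at
``(qz, qy, qx)`` with diameter ``qd``, the mean density ``Cm`` is the
mask average over the digital ball of radius ``qd/2`` centred on the
candidate (voxels falling outside the volume count as background).
Candidates with ``Cm`` below the threshold (default 0.8) lie outside or
on the rim of the parenchyma and are removed.
"""

from __future__ import annotations

import numpy as np

from .anchors import iou_matrix
from .core import Candidate, LungMask

__all__ = ["nms_iou", "lms_mean_density", "lms_filter",
           "NMS_IOU_THRESHOLD", "CM_THRESHOLD"]

NMS_IOU_THRESHOLD = 0.001
CM_THRESHOLD = 0.8


def nms_iou(candidates: list[Candidate],
            iou_threshold: float = NMS_IOU_THRESHOLD) -> list[Candidate]:
    """Keep the highest-probability candidate of each overlapping group."""
    if len(candidates) <= 1:
        return list(candidates)
    order = sorted(range(len(candidates)),
                   key=lambda i: -candidates[i].probability)
    boxes = np.asarray([candidates[i].box for i in order], float)
    keep: list[int] = []
    alive = np.ones(len(order), bool)
    for i in range(len(order)):
        if not alive[i]:
            continue
        keep.append(order[i])
        rest = np.flatnonzero(alive[i + 1:]) + i + 1
        if rest.size:
            ious = iou_matrix(boxes[i][None], boxes[rest])[0]
            alive[rest[ious > iou_threshold]] = False
    return [candidates[i] for i in keep]


def lms_mean_density(candidate: Candidate, mask: LungMask) -> float:
    """Mean lung-mask density over the candidate's digital sphere."""
    qd = candidate.diameter
    if qd <= 0:
        raise ValueError("candidate diameter must be positive")
    r = qd / 2.0
    center = np.asarray(candidate.center, float)
    grid = np.asarray(mask.grid)
    lo = np.floor(center - r).astype(int)
    hi = np.ceil(center + r).astype(int) + 1
    zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                             indexing="ij")
    inside = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
              + (xx - center[2]) ** 2) * (4.0 / qd**2) <= 1.0
    v_sphere = int(inside.sum())
    if v_sphere == 0:
        # degenerate sub-voxel sphere: fall back to the nearest voxel
        p = np.round(center).astype(int)
        if np.all(p >= 0) and np.all(p < grid.shape):
            return float(grid[tuple(p)])
        return 0.0
    valid = (inside
             & (zz >= 0) & (zz < grid.shape[0])
             & (yy >= 0) & (yy < grid.shape[1])
             & (xx >= 0) & (xx < grid.shape[2]))
    total = grid[zz[valid], yy[valid], xx[valid]].sum()
    return float(total) / v_sphere


def lms_filter(candidates: list[Candidate], mask: LungMask,
               cm_threshold: float = CM_THRESHOLD) -> list[Candidate]:
    """Keep candidates with mean sphere density Cm >= threshold."""
    kept = []
    for c in candidates:
        cm = lms_mean_density(c, mask)
        c.mean_density = cm
        if cm >= cm_threshold:
            kept.append(c)
    return kept
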