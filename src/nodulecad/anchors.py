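"""Multi-scale anchor grid, 3D IoU, label assignment, offset coding.

Anchors are cubes ``(z, y, x, d)`` in patch-voxel units.  The fine
scale (stride 4, "S2") carries diameters {5, 8, 11} for small nodules;
the coarse scale (stride 8, "S3") carries {15, 21} for large ones.
Anchor centers sit at ``stride * (i + 1/2)`` per axis, and the flat
ordering is scale-major, then grid point (z, y, x lexicographic), then
diameter — the same order the detector head emits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SCALES",
    "AnchorGrid",
    "LabelAssignment",
    "build_anchor_grid",
    "iou_3d",
    "iou_matrix",
    "assign_labels",
    "encode_offsets",
    "decode_offsets",
    "POSITIVE_IOU",
    "NEGATIVE_IOU",
    "N_NEGATIVES",
]

#: scale name -> (stride, anchor diameters in voxels)
SCALES: dict[str, tuple[int, tuple[float, ...]]] = {
    "S2": (4, (5.0, 8.0, 11.0)),
    "S3": (8, (15.0, 21.0)),
}

POSITIVE_IOU = 0.5
NEGATIVE_IOU = 0.02
N_NEGATIVES = 4000


@dataclass
class AnchorGrid:
    patch_shape: tuple[int, int, int]
    boxes: np.ndarray          # (A, 4) float32: z, y, x, d
    scale_of: np.ndarray       # (A,) 0 for S2, 1 for S3
    grid_shapes: dict[str, tuple[int, int, int]]

    @property
    def n_anchors(self) -> int:
        return self.boxes.shape[0]


def build_anchor_grid(patch_shape) -> AnchorGrid:
    """Anchor boxes for a patch whose edges are divisible by 8."""
    patch_shape = tuple(int(s) for s in patch_shape)
    if any(s % 8 for s in patch_shape):
        raise ValueError(f"patch shape {patch_shape} must be divisible by 8")
    all_boxes, all_scales = [], []
    grid_shapes = {}
    for si, (name, (stride, diameters)) in enumerate(SCALES.items()):
        gshape = tuple(s // stride for s in patch_shape)
        grid_shapes[name] = gshape
        zz, yy, xx = np.meshgrid(
            *[stride * (np.arange(g) + 0.5) for g in gshape], indexing="ij"
        )
        centers = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
        n_pts = centers.shape[0]
        # grid-point-major, diameter-minor
        boxes = np.empty((n_pts * len(diameters), 4), np.float32)
        boxes[:, :3] = np.repeat(centers, len(diameters), axis=0)
        boxes[:, 3] = np.tile(np.asarray(diameters, np.float32), n_pts)
        all_boxes.append(boxes)
        all_scales.append(np.full(boxes.shape[0], si, np.int8))
    return AnchorGrid(
        patch_shape=patch_shape,
        boxes=np.concatenate(all_boxes),
        scale_of=np.concatenate(all_scales),
        grid_shapes=grid_shapes,
    )


def _overlap_1d(c1, d1, c2, d2):
    lo = np.maximum(c1 - d1 / 2.0, c2 - d2 / 2.0)
    hi = np.minimum(c1 + d1 / 2.0, c2 + d2 / 2.0)
    return np.maximum(hi - lo, 0.0)


def iou_3d(a, b) -> float:
    """IoU of two axis-aligned cubes given as (z, y, x, d)."""
    return float(iou_matrix(np.asarray(a, float)[None], np.asarray(b, float)[None])[0, 0])


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU, (Na, 4) x (Nb, 4) -> (Na, Nb)."""
    a = np.asarray(boxes_a, float)
    b = np.asarray(boxes_b, float)
    if np.any(a[:, 3] <= 0) or np.any(b[:, 3] <= 0):
        raise ValueError("box diameters must be positive")
    inter = np.ones((a.shape[0], b.shape[0]))
    for axis in range(3):
        inter = inter * _overlap_1d(
            a[:, axis, None], a[:, 3, None], b[None, :, axis], b[None, :, 3]
        )
    vol_a = a[:, 3] ** 3
    vol_b = b[:, 3] ** 3
    union = vol_a[:, None] + vol_b[None, :] - inter
    return inter / union


@dataclass
class LabelAssignment:
    """Partition of (a subset of) the anchor grid for one training patch."""

    positives: list[tuple[int, np.ndarray, np.ndarray]]  # (anchor idx, label box, offset)
    negatives: np.ndarray  # anchor indices
    ignored: np.ndarray    # anchor indices

    @property
    def positive_indices(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.positives], dtype=np.intp)

    @property
    def offsets(self) -> np.ndarray:
        if not self.positives:
            return np.zeros((0, 4), np.float32)
        return np.stack([p[2] for p in self.positives]).astype(np.float32)


def assign_labels(grid: AnchorGrid, annotations, rng: np.random.Generator
                  ) -> LabelAssignment:
    """Per-label positive anchors, 4000 easy negatives, the rest ignored.

    For each label one anchor is drawn uniformly among those with
    IoU >= 0.5, falling back to the argmax-IoU anchor (ties broken by
    lowest index).  Negatives are sampled without replacement from
    anchors with IoU <= 0.02 against every label.
    """
    labels = np.asarray([np.asarray(a, float)[:4] for a in annotations], float)
    A = grid.n_anchors
    positives: list[tuple[int, np.ndarray, np.ndarray]] = []
    if labels.size:
        ious = iou_matrix(grid.boxes, labels)  # (A, L)
        for j in range(labels.shape[0]):
            eligible = np.flatnonzero(ious[:, j] >= POSITIVE_IOU)
            if eligible.size:
                idx = int(rng.choice(eligible))
            else:
                idx = int(np.argmax(ious[:, j]))
            offset = encode_offsets(labels[j], grid.boxes[idx])
            positives.append((idx, labels[j], offset))
        neg_eligible = np.flatnonzero(ious.max(axis=1) <= NEGATIVE_IOU)
    else:
        neg_eligible = np.arange(A)
    pos_idx = {p[0] for p in positives}
    neg_eligible = neg_eligible[~np.isin(neg_eligible, list(pos_idx))] \
        if pos_idx else neg_eligible
    if neg_eligible.size > N_NEGATIVES:
        negatives = rng.choice(neg_eligible, size=N_NEGATIVES, replace=False)
        negatives = np.sort(negatives)
    else:
        negatives = neg_eligible
    selected = np.concatenate([np.asarray(sorted(pos_idx), dtype=np.intp),
                               negatives.astype(np.intp)])
    ignored = np.setdiff1d(np.arange(A), selected, assume_unique=False)
    return LabelAssignment(positives=positives,
                           negatives=negatives.astype(np.intp),
                           ignored=ignored.astype(np.intp))


def encode_offsets(label_box, anchor_box) -> np.ndarray:
    """Regression target: r_i = (g_i - b_i) / b_d, r_d = ln(g_d / b_d)."""
    g = np.asarray(label_box, float)
    b = np.asarray(anchor_box, float)
    if g[3] <= 0 or b[3] <= 0:
        raise ValueError("diameters must be positive")
    r = np.empty(4)
    r[:3] = (g[:3] - b[:3]) / b[3]
    r[3] = np.log(g[3] / b[3])
    return r


def decode_offsets(offset, anchor_box) -> np.ndarray:
    """Exact inverse of :func:`encode_offsets`."""
    r = np.asarray(offset, float)
    b = np.asarray(anchor_box, float)
    if b[3] <= 0:
        raise ValueError("anchor diameter must be positive")
    g = np.empty(4)
    g[:3] = r[:3] * b[3] + b[:3]
    g[3] = np.exp(r[3]) * b[3]
    return g
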