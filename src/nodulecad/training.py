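"""Training loops for the detector (MSFD-Net) and scorer (CS-Net).

Detector training samples one 96^3 (configurable) patch per nodule
appearance and epoch: each annotated nodule is loaded ``lf = 1 +
floor(3 d / 10)`` times per epoch (diameter-weighted oversampling of
the rarer large nodules), the crop is placed so the target nodule lands
uniformly inside the patch with a margin of half its diameter, and
online augmentation (random flips, axis transposition, zoom in
[0.9, 1.1]) is applied.  Patches in a mini-batch share one merged label
assignment, so OHNM mines negatives across the whole batch.

Scorer training draws, before every epoch, a fresh random 70% of the
negative patches, then minimises the focal loss with OHNM (beta = 5 by
default for the scorer, 10 for the detector).

All data sampling is driven by a single seeded generator; remaining
nondeterminism is limited to floating-point reduction order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .anchors import LabelAssignment, assign_labels, build_anchor_grid
from .core import CTVolume
from .fpr import CandidatePatch
from .losses import (LossConfig, classification_loss, focal_loss, ohnm_select,
                     regression_loss, total_loss)
from .networks import CSNet, MSFDNet
from .nn import Adam, Tensor, gather, sigmoid
from .preprocessing import FILL_GRAY

__all__ = [
    "TrainConfig",
    "TrainLogRecord",
    "load_frequency",
    "sample_training_patch",
    "DetectorDataset",
    "train_detector",
    "train_scorer",
    "lr_at_epoch",
    "score_auc",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 10
    epochs: int = 300
    lr_initial: float = 1e-3
    #: (epoch, factor): after `epoch` epochs the lr becomes lr_initial*factor
    lr_milestones: tuple[tuple[int, float], ...] = ((60, 0.1), (120, 0.05), (180, 0.01))
    beta_ohnm: float = 10.0
    seed: int = 0
    neg_resample_fraction: float = 0.7  # CS-Net only
    alpha: float = 0.5
    gamma: float = 2.0

    def __post_init__(self):
        if any(f <= 0 or f > 1 for _, f in self.lr_milestones):
            raise ValueError("milestone factors must be in (0,1]")
        epochs = [e for e, _ in self.lr_milestones]
        if epochs != sorted(epochs):
            raise ValueError("milestones must be increasing")

    @property
    def loss_config(self) -> LossConfig:
        return LossConfig(alpha=self.alpha, gamma=self.gamma, beta=self.beta_ohnm)


@dataclass
class TrainLogRecord:
    epoch: int
    cls_loss: float
    reg_loss: float
    total_loss: float
    lr: float


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate in effect during 1-based ``epoch``."""
    factor = 1.0
    for milestone, f in cfg.lr_milestones:
        if epoch > milestone:
            factor = f
    return cfg.lr_initial * factor


def load_frequency(d: float) -> int:
    """Per-epoch repetition count of a nodule of diameter ``d`` mm."""
    if d <= 0:
        raise ValueError("diameter must be positive")
    return 1 + math.floor(3.0 * d / 10.0)


def _crop_padded_f(grid, lo, shape, fill=FILL_GRAY):
    out = np.full(shape, fill, dtype=grid.dtype)
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(lo + shape, grid.shape)
    if np.any(src_lo >= src_hi):
        return out
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    out[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = \
        grid[tuple(slice(a, b) for a, b in zip(src_lo, src_hi))]
    return out


def sample_training_patch(pre_image: CTVolume, target_annotation,
                          rng: np.random.Generator,
                          patch_shape=(96, 96, 96),
                          all_annotations=None,
                          augment: bool = True,
                          zoom_range=(0.9, 1.1)):
    """Random nodule-centred crop with online augmentation.

    ``target_annotation`` and ``all_annotations`` are (z, y, x, d) boxes
    in pre-image voxels.  Returns ``(patch uint8, boxes in patch
    coordinates)``; the target nodule is always inside the patch with a
    margin of at least half its diameter.
    """
    patch_shape = np.asarray(patch_shape, int)
    target = np.asarray(target_annotation, float)
    if all_annotations is None:
        all_annotations = [target]
    grid = np.asarray(pre_image.grid)

    margin = np.minimum(target[3] / 2.0 + 1.0, patch_shape / 2.0 - 1.0)
    offset = rng.uniform(margin, patch_shape - margin)  # nodule pos in patch
    lo = np.round(target[:3] - offset).astype(int)
    patch = _crop_padded_f(grid, lo, tuple(patch_shape))

    boxes = []
    for ann in all_annotations:
        b = np.asarray(ann, float).copy()
        b[:3] -= lo
        if np.all(b[:3] >= 0) and np.all(b[:3] < patch_shape):
            boxes.append(b)

    if augment:
        f = rng.uniform(*zoom_range)
        if abs(f - 1.0) > 1e-3:
            zoomed = ndimage.zoom(patch.astype(np.float32), f, order=1,
                                  mode="nearest", grid_mode=True)
            lo2 = (np.asarray(zoomed.shape) - patch_shape) // 2
            patch = np.clip(np.round(
                _crop_padded_f(zoomed, lo2, tuple(patch_shape))), 0, 255
            ).astype(np.uint8)
            newboxes = []
            for b in boxes:
                b = b.copy()
                b[:3] = (b[:3] + 0.5) * f - 0.5 - lo2
                b[3] *= f
                if np.all(b[:3] >= 0) and np.all(b[:3] < patch_shape):
                    newboxes.append(b)
            boxes = newboxes
        perm = rng.permutation(3)
        patch = np.ascontiguousarray(patch.transpose(perm))
        boxes = [np.concatenate([b[:3][perm], b[3:]]) for b in boxes]
        for axis in range(3):
            if rng.random() < 0.5:
                patch = np.flip(patch, axis=axis)
                for b in boxes:
                    b[axis] = patch_shape[axis] - 1 - b[axis]
        patch = np.ascontiguousarray(patch)
    return patch.astype(np.uint8), boxes


class DetectorDataset:
    """Per-epoch patch sampler over a set of preprocessed scans.

    ``scans`` is a list of ``(pre_image, annotations)`` with annotations
    as (z, y, x, d) boxes in pre-image voxels (1 mm isotropic, so voxel
    diameters equal mm).
    """

    def __init__(self, scans, patch_shape=(96, 96, 96), augment: bool = True,
                 patches_per_epoch: int | None = None):
        self.scans = list(scans)
        self.patch_shape = tuple(patch_shape)
        self.augment = augment
        self.patches_per_epoch = patches_per_epoch

    def sample_epoch(self, rng: np.random.Generator):
        samples = []
        for pre_image, annotations in self.scans:
            annotations = [np.asarray(a, float) for a in annotations]
            for ann in annotations:
                for _ in range(load_frequency(ann[3])):
                    samples.append((pre_image, ann, annotations))
        order = rng.permutation(len(samples))
        if self.patches_per_epoch is not None:
            # lf still acts as the sampling weight; the epoch just visits
            # a random subset of the weighted pool
            order = order[: self.patches_per_epoch]
        out = []
        for i in order:
            pre_image, ann, all_ann = samples[i]
            out.append(sample_training_patch(pre_image, ann, rng,
                                             self.patch_shape, all_ann,
                                             augment=self.augment))
        return out


def _merge_assignments(assignments: list[LabelAssignment], n_anchors: int
                       ) -> LabelAssignment:
    positives, negatives, ignored = [], [], []
    for b, a in enumerate(assignments):
        off = b * n_anchors
        positives += [(idx + off, box, r) for idx, box, r in a.positives]
        negatives.append(a.negatives + off)
        ignored.append(a.ignored + off)
    return LabelAssignment(positives=positives,
                           negatives=np.concatenate(negatives),
                           ignored=np.concatenate(ignored))


def train_detector(dataset: DetectorDataset, model: MSFDNet, cfg: TrainConfig
                   ) -> tuple[MSFDNet, list[TrainLogRecord]]:
    """Adam training of the detector; returns the model and a loss log."""
    rng = np.random.default_rng(cfg.seed)
    grid = build_anchor_grid(dataset.patch_shape)
    opt = Adam(model.parameters(), lr=cfg.lr_initial)
    log: list[TrainLogRecord] = []
    loss_cfg = cfg.loss_config
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = lr_at_epoch(cfg, epoch)
        model.train()
        samples = dataset.sample_epoch(rng)
        cls_sum = reg_sum = tot_sum = 0.0
        n_batches = 0
        for start in range(0, len(samples), cfg.batch_size):
            batch = samples[start:start + cfg.batch_size]
            x = np.stack([p.astype(np.float32) / 255.0 for p, _ in batch])[:, None]
            assignments = [assign_labels(grid, boxes, rng) for _, boxes in batch]
            merged = _merge_assignments(assignments, grid.n_anchors)
            opt.zero_grad()
            cls_logits, reg = model(x)
            probs = sigmoid(cls_logits.reshape(-1))
            l_cls = classification_loss(probs, merged, loss_cfg)
            l_reg = regression_loss(reg.reshape(-1, 4), merged)
            loss = total_loss(l_cls, l_reg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"detector training diverged at epoch {epoch} "
                    f"(loss={loss.data}); log so far: {len(log)} records")
            loss.backward()
            opt.step()
            cls_sum += float(l_cls.data)
            reg_sum += float(l_reg.data) if isinstance(l_reg, Tensor) else float(l_reg)
            tot_sum += float(loss.data)
            n_batches += 1
        n_batches = max(n_batches, 1)
        log.append(TrainLogRecord(epoch, cls_sum / n_batches,
                                  reg_sum / n_batches, tot_sum / n_batches,
                                  opt.lr))
    model.eval()
    return model, log


def train_scorer(patches: list[CandidatePatch], model: CSNet, cfg: TrainConfig
                 ) -> tuple[CSNet, list[TrainLogRecord]]:
    """Focal-loss training of CS-Net on labelled candidate patches."""
    rng = np.random.default_rng(cfg.seed)
    pos = [p for p in patches if p.label == 1]
    neg = [p for p in patches if p.label == 0]
    opt = Adam(model.parameters(), lr=cfg.lr_initial)
    loss_cfg = cfg.loss_config
    log: list[TrainLogRecord] = []
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = lr_at_epoch(cfg, epoch)
        model.train()
        n_neg = int(cfg.neg_resample_fraction * len(neg))
        chosen = [neg[i] for i in rng.choice(len(neg), n_neg, replace=False)] \
            if neg else []
        epoch_set = pos + chosen
        order = rng.permutation(len(epoch_set))
        loss_sum, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [epoch_set[i] for i in idx]
            x = np.stack([p.grid.astype(np.float32) / 255.0 for p in batch])[:, None]
            labels = np.asarray([p.label for p in batch], np.float32)
            opt.zero_grad()
            probs = model(x).reshape(-1)
            k = int(labels.sum())
            neg_idx = np.flatnonzero(labels == 0)
            mined = neg_idx[ohnm_select(probs.data[neg_idx], k, loss_cfg)] \
                if neg_idx.size else np.zeros(0, np.intp)
            sel = np.concatenate([np.flatnonzero(labels == 1), mined])
            if sel.size == 0:
                continue
            sel_labels = labels[sel]
            loss = focal_loss(gather(probs, sel), sel_labels, loss_cfg).sum() \
                * (1.0 / sel.size)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"scorer training diverged at epoch {epoch}")
            loss.backward()
            opt.step()
            loss_sum += float(loss.data)
            n_batches += 1
        n_batches = max(n_batches, 1)
        log.append(TrainLogRecord(epoch, loss_sum / n_batches, 0.0,
                                  loss_sum / n_batches, opt.lr))
    model.eval()
    return model, log


def score_auc(model: CSNet, patches: list[CandidatePatch]) -> float:
    """Rank-based AUC of the scorer on labelled patches."""
    model.eval()
    labels = np.asarray([p.label for p in patches])
    scores = np.concatenate([
        model(np.concatenate([p.tensor_input
                              for p in patches[i:i + 32]])).data.reshape(-1)
        for i in range(0, len(patches), 32)])
    pos, neg = scores[labels == 1], scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes")
    greater = (pos[:, None] > neg[None, :]).mean()
    ties = (pos[:, None] == neg[None, :]).mean()
    return float(greater + 0.5 * ties)
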