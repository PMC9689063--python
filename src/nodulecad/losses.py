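"""Training losses: focal classification loss with online hard negative
mining (OHNM) and smooth-L1 regression loss.

The focal loss here is the standard nonnegative form

    L_f(p*, 1) = -alpha     * (1 - p*)^gamma * ln(p*)
    L_f(p*, 0) = -(1-alpha) * (p*)^gamma     * ln(1 - p*)

with natural logarithms.  OHNM keeps only the ``beta * K`` negatives
with the highest predicted probability (K = number of positives), and
the classification loss averages the focal loss over the positives plus
the mined negatives.  Regression is per-component smooth L1 (squared
below 1, absolute above), summed over (z, y, x, d) and averaged over
positives.

All loss functions accept plain ndarrays or autodiff tensors; training
passes tensors so gradients flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .anchors import LabelAssignment
from .nn import Tensor, absolute, gather, log

__all__ = [
    "LossConfig",
    "focal_loss",
    "ohnm_select",
    "classification_loss",
    "smooth_l1",
    "regression_loss",
    "total_loss",
]

_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.5   # positive/negative balance
    gamma: float = 2.0   # focusing factor
    beta: float = 5.0    # negatives-per-positive ratio for OHNM

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")


def _clamp(p_star):
    """Keep probabilities away from {0,1} so the log stays finite."""
    if isinstance(p_star, Tensor):
        return p_star * (1.0 - 2.0 * _EPS) + _EPS
    return np.clip(p_star, _EPS, 1.0 - _EPS)


def focal_loss(p_star, p, cfg: LossConfig = LossConfig()):
    """Elementwise focal loss; ``p`` is the {0,1} class label."""
    ps = _clamp(p_star)
    p = np.asarray(p, dtype=np.float32)
    pos = -cfg.alpha * (1.0 - ps) ** cfg.gamma * log(ps)
    neg = -(1.0 - cfg.alpha) * ps**cfg.gamma * log(1.0 - ps)
    return pos * p + neg * (1.0 - p)


def ohnm_select(neg_probs, n_positives: int, cfg: LossConfig = LossConfig()
                ) -> np.ndarray:
    """Indices of the top-(beta*K) hardest negatives, ties by index."""
    if n_positives < 0:
        raise ValueError("positive count must be nonnegative")
    probs = np.asarray(neg_probs, dtype=float)
    k = min(int(cfg.beta * n_positives), probs.size)
    if k == 0:
        return np.zeros(0, dtype=np.intp)
    order = np.argsort(-probs, kind="stable")
    return order[:k]


def classification_loss(cls_probs, assignment: LabelAssignment,
                        cfg: LossConfig = LossConfig()):
    """Mean focal loss over positives + OHNM-mined negatives.

    ``cls_probs`` holds per-anchor probabilities aligned with the
    anchor-grid ordering (shape (A,) or (A,1)).
    """
    is_tensor = isinstance(cls_probs, Tensor)
    flat = cls_probs.reshape(-1) if is_tensor else np.asarray(cls_probs).reshape(-1)
    data = flat.data if is_tensor else flat
    pos_idx = assignment.positive_indices
    k = pos_idx.size
    neg_pool = assignment.negatives
    mined = neg_pool[ohnm_select(data[neg_pool], k, cfg)] if neg_pool.size else \
        np.zeros(0, dtype=np.intp)
    n = k + mined.size
    if n == 0:
        warnings.warn("classification_loss: no samples selected; returning 0")
        return Tensor(0.0) if is_tensor else 0.0
    idx = np.concatenate([pos_idx, mined])
    labels = np.concatenate([np.ones(k, np.float32), np.zeros(mined.size, np.float32)])
    selected = gather(flat, idx) if is_tensor else flat[idx]
    return focal_loss(selected, labels, cfg).sum() * (1.0 / n)


def smooth_l1(r_star, r):
    """Per-component: (r*-r)^2 if |r*-r| < 1 else |r*-r|."""
    diff = r_star - r if isinstance(r_star, Tensor) else \
        np.asarray(r_star, float) - np.asarray(r, float)
    d_data = diff.data if isinstance(diff, Tensor) else diff
    quad = (np.abs(d_data) < 1.0).astype(np.float32)
    return diff**2 * quad + absolute(diff) * (1.0 - quad)


def regression_loss(reg, assignment: LabelAssignment):
    """Smooth-L1 summed over the four offsets, averaged over positives."""
    pos_idx = assignment.positive_indices
    k = pos_idx.size
    if k == 0:
        return Tensor(0.0) if isinstance(reg, Tensor) else 0.0
    targets = assignment.offsets
    if isinstance(reg, Tensor):
        pred = gather(reg.reshape(-1, 4), pos_idx)
    else:
        pred = np.asarray(reg, float).reshape(-1, 4)[pos_idx]
    return smooth_l1(pred, targets).sum() * (1.0 / k)


def total_loss(cls_loss, reg_loss):
    """L_total = L_cls + L_reg (unweighted sum)."""
    return cls_loss + reg_loss
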