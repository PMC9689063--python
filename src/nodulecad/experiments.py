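"""A desk-scale end-to-end study on synthetic phantoms.

This module wires the whole system together at a size a single CPU can
train: generate phantoms, train a width-halved detector on 48^3
patches, train a compact candidate scorer on the detector's own
candidates, and evaluate the one-stage and two-stage pipelines on
held-out phantoms.

Training uses offline patch extraction (a fixed, pre-sampled patch set
rather than fresh crops every epoch) in two phases: a uniform phase
over the diameter-weighted patch pool, then a hard-example phase whose
patch set oversamples nodules the current model still scores poorly —
a sample-level analogue of the online hard negative mining used inside
each batch.  Problem sizes (phantom count and edge, patch counts,
epochs) are deliberately small; they are the study's stated conditions,
not tuned quantities.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .anchors import assign_labels, build_anchor_grid, iou_matrix
from .core import CTVolume, LungMask
from .evaluation import cad_performance, hit_test
from .fpr import _crop_padded, offline_augment, score_and_filter
from .networks import (CSNet, MSFDNet, MSFEConfig, ScorerConfig,
                       default_detector_config)
from .nn import sigmoid
from .phantom import PhantomSpec, generate_phantom
from .pipeline import InferenceConfig, detect_candidates
from .preprocessing import preprocess_scan
from .suppression import lms_filter, nms_iou
from .training import (DetectorDataset, TrainConfig, sample_training_patch,
                       train_detector, train_scorer)

__all__ = ["ReducedStudyConfig", "StudyScan", "ReducedStudyResult",
           "make_study_scans", "FixedPatchSet", "train_reduced_detector",
           "run_reduced_study"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReducedStudyConfig:
    """Conditions of the scaled-down experiment."""

    n_train: int = 30
    n_calibration: int = 6   # of n_train, held out for threshold calibration
    n_test: int = 10
    volume_edge: int = 96
    nodules_per_scan: tuple[int, int] = (3, 5)       # inclusive range
    diameter_range: tuple[float, float] = (5.0, 18.0)
    n_vessels: int = 6
    patch_edge: int = 48
    width_scale: float = 0.5
    detector_dropout: float = 0.0   # no regularisation in short runs
    phase1_patches: int = 96
    phase1_epochs: int = 22
    phase2_patches: int = 96
    phase2_epochs: int = 8
    batch_size: int = 2
    lr_phase1: float = 1.5e-3
    lr_phase2: float = 5e-4
    base_cth: float = 0.3       # pool threshold; operating Cth is calibrated
    stride: int = 24
    max_per_tile: int = 150     # pre-suppression cap per tile
    fps_target: float = 1.8     # calibration-scan FPs/scan target for Cth
    extra_neg_cth: float = 0.15  # permissive pass for easy scorer negatives
    extra_neg_stride: int = 40
    scorer_reps: int = 2
    scorer_neg_cap: int = 700
    scorer_epochs: int = 6
    scorer_batch: int = 64
    scorer_config: ScorerConfig = field(default_factory=lambda: ScorerConfig(
        msfe=MSFEConfig(encoder_widths=(4, 6, 10, 16, 20),
                        blocks_per_layer=(1, 1, 1, 1), decoder_width=8,
                        dropout_p=0.1, bn_eval_stats="running"),
        agg_channels=32, hidden=16))


@dataclass
class StudyScan:
    scan_id: str
    pre_image: CTVolume
    lung_mask: LungMask
    boxes: list[np.ndarray]  # (z,y,x,d) in pre-image voxels


def make_study_scans(cfg: ReducedStudyConfig, n: int, seed0: int
                     ) -> list[StudyScan]:
    """Generate and preprocess ``n`` phantoms with seeds seed0..seed0+n-1."""
    scans = []
    for i in range(n):
        r = np.random.default_rng(seed0 + i)
        spec = PhantomSpec(
            volume_shape=(cfg.volume_edge,) * 3,
            n_nodules=int(r.integers(cfg.nodules_per_scan[0],
                                     cfg.nodules_per_scan[1] + 1)),
            diameter_range=cfg.diameter_range,
            n_vessels=cfg.n_vessels,
            seed=seed0 + i,
            scan_id=f"study-{seed0 + i}",
        )
        vol, _, anns = generate_phantom(spec)
        pre, mask, offset = preprocess_scan(vol)
        boxes = []
        for a in anns:
            v = a.to_voxel(vol)
            boxes.append(np.asarray([*(np.asarray(v.center) - offset),
                                     v.diameter]))
        scans.append(StudyScan(spec.scan_id, pre, mask, boxes))
    return scans


class FixedPatchSet:
    """Offline-extracted training patches with a `sample_epoch` interface."""

    def __init__(self, patches, patch_shape):
        self._patches = list(patches)
        self.patch_shape = tuple(patch_shape)

    def sample_epoch(self, rng: np.random.Generator):
        order = rng.permutation(len(self._patches))
        return [self._patches[i] for i in order]


def _nodule_probability(model, scan: StudyScan, box, grid) -> float:
    """Detector probability near one nodule, on a centred crop."""
    half = grid.patch_shape[0] // 2
    crop = _crop_padded(np.asarray(scan.pre_image.grid), box[:3], half)
    local = box.copy()
    local[:3] = box[:3] - (np.round(box[:3]).astype(int) - half)
    ious = iou_matrix(grid.boxes, local[None])[:, 0]
    cls, _ = model(crop[None, None].astype(np.float32) / 255.0)
    probs = sigmoid(cls.data.reshape(-1))
    return float(probs[np.argsort(-ious)[:8]].max())


def train_reduced_detector(scans: list[StudyScan], cfg: ReducedStudyConfig,
                           seed: int) -> MSFDNet:
    """Two-phase fixed-set training of the width-halved detector."""
    rng = np.random.default_rng(seed)
    shape = (cfg.patch_edge,) * 3
    dataset = DetectorDataset([(s.pre_image, s.boxes) for s in scans],
                              patch_shape=shape)
    pool = dataset.sample_epoch(rng)
    sel = rng.permutation(len(pool))[: cfg.phase1_patches]
    phase1 = FixedPatchSet([pool[i] for i in sel], shape)
    det_cfg = default_detector_config().scaled(cfg.width_scale)
    det_cfg = dataclasses.replace(
        det_cfg, msfe=dataclasses.replace(det_cfg.msfe,
                                          dropout_p=cfg.detector_dropout))
    model = MSFDNet(det_cfg, seed=seed)
    model, _ = train_detector(phase1, model, TrainConfig(
        batch_size=cfg.batch_size, epochs=cfg.phase1_epochs,
        lr_initial=cfg.lr_phase1, lr_milestones=(), beta_ohnm=10.0,
        seed=seed))

    # hard-example phase: oversample nodules the model still misses
    model.eval()
    grid = build_anchor_grid(shape)
    entries = [(s, b) for s in scans for b in s.boxes]
    probs = np.asarray([_nodule_probability(model, s, b, grid)
                        for s, b in entries])
    log.info("nodule probability quartiles after phase 1: %s",
             np.percentile(probs, [25, 50, 75]).round(2))
    weights = np.maximum(1.05 - probs, 0.05)
    weights /= weights.sum()
    idx = rng.choice(len(entries), cfg.phase2_patches, p=weights)
    hard = []
    for i in idx:
        s, b = entries[i]
        hard.append(sample_training_patch(s.pre_image, b, rng, shape, s.boxes))
    model, _ = train_detector(FixedPatchSet(hard, shape), model, TrainConfig(
        batch_size=cfg.batch_size, epochs=cfg.phase2_epochs,
        lr_initial=cfg.lr_phase2, lr_milestones=(), beta_ohnm=10.0,
        seed=seed + 1))
    return model


def _stage1(scans, model, cfg: ReducedStudyConfig, cth, stride):
    icfg = InferenceConfig(patch_edge=cfg.patch_edge, stride=stride,
                           candidate_threshold=cth,
                           max_per_tile=cfg.max_per_tile)
    out = {}
    for s in scans:
        cands = detect_candidates(s.pre_image, model, icfg, s.scan_id)
        cands = lms_filter(cands, s.lung_mask)
        out[s.scan_id] = nms_iou(cands)
    return out


def calibrate_cth(train_cands, annotations, fps_target: float,
                  floor: float) -> float:
    """Operating-point selection on the training scans: the smallest
    probability threshold (hence highest sensitivity) whose training
    FPs/scan does not exceed the target.

    Candidate-to-annotation attribution is threshold-independent, so it
    is computed once and the sweep reduces to a cumulative count.
    """
    from .evaluation import _attribute_candidates

    n_scans = max(len(annotations), 1)
    conf, is_fp = [], []
    for sid, cl in train_cands.items():
        attr = _attribute_candidates(cl, annotations.get(sid, []), [])
        conf.extend(c.probability for c in cl)
        is_fp.extend(a == -1 for a in attr)
    if not conf:
        return floor
    conf = np.asarray(conf)
    is_fp = np.asarray(is_fp)
    order = np.argsort(-conf, kind="stable")
    cum_fp = np.cumsum(is_fp[order])
    ok = np.flatnonzero(cum_fp / n_scans <= fps_target)
    if ok.size == 0:
        return max(float(conf.max()), floor)
    # keep everything down to the lowest confidence still within target
    return max(float(conf[order][ok[-1]]), floor)


def calibrate_cs(scorer, scans, cands, cth: float) -> float:
    """Score threshold from calibration candidates: as high as the FP
    score distribution allows while every calibration true positive
    keeps a 10% margin."""
    tp_scores, fp_scores = [], []
    for s in scans:
        kept = [c for c in cands[s.scan_id] if c.probability >= cth]
        if not kept:
            continue
        for c in score_and_filter(kept, s.pre_image, scorer, -1.0):
            (tp_scores if any(hit_test(c, b) for b in s.boxes)
             else fp_scores).append(c.score)
    if not tp_scores:
        return 0.005
    # halve the lowest calibration-TP score: held-out true positives can
    # score below the calibration minimum, so the margin is generous
    ceiling = 0.5 * min(tp_scores)
    target = np.percentile(fp_scores, 25) if fp_scores else 0.005
    return float(np.clip(min(ceiling, max(target, 0.002)), 0.002, 0.15))


@dataclass
class ReducedStudyResult:
    one_stage: tuple[float, float, float]   # FPs/scan, sensitivity, precision
    two_stage: tuple[float, float, float]
    detector: MSFDNet
    scorer: CSNet
    cth: float
    cs_threshold: float
    test_candidates: dict[str, list]
    test_candidates_scored: dict[str, list]
    annotations: dict[str, list]


def run_reduced_study(seed: int = 0,
                      cfg: ReducedStudyConfig = ReducedStudyConfig()
                      ) -> ReducedStudyResult:
    """Run the full scaled-down experiment; deterministic under ``seed``."""
    all_train = make_study_scans(cfg, cfg.n_train, 1000 + seed)
    fit_scans = all_train[: cfg.n_train - cfg.n_calibration]
    cal_scans = all_train[cfg.n_train - cfg.n_calibration:]
    test_scans = make_study_scans(cfg, cfg.n_test, 100000 + seed)

    detector = train_reduced_detector(fit_scans, cfg, seed)

    # candidate pools at a permissive threshold; the operating point is
    # calibrated on training scans the patch set never saw
    fit_cands = _stage1(fit_scans, detector, cfg, cfg.base_cth, cfg.stride)
    cal_cands = _stage1(cal_scans, detector, cfg, cfg.base_cth, cfg.stride)
    cal_ann = {s.scan_id: s.boxes for s in cal_scans}
    cth = calibrate_cth(cal_cands, cal_ann, cfg.fps_target, cfg.base_cth)
    log.info("calibrated Cth = %.3f", cth)

    pos, neg = [], []
    pre_by = {s.scan_id: s.pre_image for s in fit_scans}
    for s in fit_scans:
        for c in fit_cands[s.scan_id]:
            (pos if any(hit_test(c, b) for b in s.boxes) else neg).append(c)
    # a permissive, coarser pass adds easy negatives so the scorer's
    # low-score tail is well anchored
    extra = _stage1(fit_scans, detector, cfg, cfg.extra_neg_cth,
                    cfg.extra_neg_stride)
    for s in fit_scans:
        for c in extra[s.scan_id]:
            if c.probability < cfg.base_cth and \
                    not any(hit_test(c, b) for b in s.boxes):
                neg.append(c)
    log.info("scorer training candidates: %d TP, %d FP", len(pos), len(neg))
    rng = np.random.default_rng(seed + 7)
    if len(neg) > cfg.scorer_neg_cap:
        neg = [neg[i] for i in rng.choice(len(neg), cfg.scorer_neg_cap,
                                          replace=False)]
    patches = offline_augment(pos, pre_by, rng, neg, reps=cfg.scorer_reps)
    scorer = CSNet(cfg.scorer_config, seed=seed)
    scorer, _ = train_scorer(patches, scorer, TrainConfig(
        batch_size=cfg.scorer_batch, epochs=cfg.scorer_epochs,
        lr_initial=1e-3, lr_milestones=(), beta_ohnm=5.0, seed=seed))
    cs_threshold = calibrate_cs(scorer, cal_scans, cal_cands, cth)
    log.info("calibrated Cs = %.4f", cs_threshold)

    # held-out evaluation at the calibrated operating point
    pool = _stage1(test_scans, detector, cfg, cfg.base_cth, cfg.stride)
    test_cands = {sid: [c for c in cl if c.probability >= cth]
                  for sid, cl in pool.items()}
    annotations = {s.scan_id: s.boxes for s in test_scans}
    one_stage = cad_performance(test_cands, annotations)

    scored = {}
    for s in test_scans:
        scored[s.scan_id] = score_and_filter(
            list(test_cands[s.scan_id]), s.pre_image, scorer, cs_threshold)
    two_stage = cad_performance(scored, annotations)
    return ReducedStudyResult(one_stage=one_stage, two_stage=two_stage,
                              detector=detector, scorer=scorer, cth=cth,
                              cs_threshold=cs_threshold,
                              test_candidates=test_cands,
                              test_candidates_scored=scored,
                              annotations=annotations)
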