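"""Detection evaluation: FROC/CPM, CAD-performance summaries,
size-stratified reporting, and the paired t-test on per-fold precision.

Hit criterion (LUNA16 convention): a candidate hits an annotation when
the Euclidean distance between centres is strictly less than the
annotation radius.  Each candidate is attributed to at most one
annotation — the nearest one covering it — so duplicate detections of a
nodule neither raise sensitivity nor count as false positives.
Candidates hitting an "excluded" annotation (irrelevant findings)
count as neither true nor false positives.

The FROC curve sweeps the candidate confidence; the seven-point CPM
summary reads the step function at the largest achieved FPs/scan not
exceeding each of {0.125, 0.25, 0.5, 1, 2, 4, 8}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Candidate, NoduleAnnotation

__all__ = [
    "CPM_FPS_POINTS",
    "FROCCurve",
    "hit_test",
    "froc_curve",
    "cpm",
    "cad_performance",
    "size_stratified",
    "paired_t",
    "t_critical",
    "SIZE_BINS",
]

CPM_FPS_POINTS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
SIZE_BINS = {"small": (3.0, 10.0), "medium": (10.0, 20.0), "large": (20.0, 30.0)}


def _ann_box(a) -> tuple[np.ndarray, float]:
    if isinstance(a, NoduleAnnotation):
        return np.asarray(a.center, float), float(a.diameter)
    arr = np.asarray(a, float)
    return arr[:3], float(arr[3])


def hit_test(candidate: Candidate, annotation) -> bool:
    """True iff the candidate centre lies inside the annotation radius."""
    center, diameter = _ann_box(annotation)
    dist = float(np.linalg.norm(np.asarray(candidate.center, float) - center))
    return dist < diameter / 2.0


@dataclass
class FROCCurve:
    """Operating points plus the seven-point CPM summary."""

    fps_per_scan: np.ndarray     # ascending
    sensitivity: np.ndarray      # matching, non-decreasing
    seven_points: dict[float, float]

    @property
    def cpm(self) -> float:
        return float(np.mean([self.seven_points[f] for f in CPM_FPS_POINTS]))


def _attribute_candidates(candidates, annotations, excluded):
    """For each candidate: index of nearest covering annotation, -1 for a
    false positive, -2 for an excluded hit."""
    ann_boxes = [_ann_box(a) for a in annotations]
    exc_boxes = [_ann_box(a) for a in excluded]
    out = np.full(len(candidates), -1, dtype=int)
    for i, cand in enumerate(candidates):
        c = np.asarray(cand.center, float)
        best, best_dist = -1, np.inf
        for j, (ctr, d) in enumerate(ann_boxes):
            dist = float(np.linalg.norm(c - ctr))
            if dist < d / 2.0 and dist < best_dist:
                best, best_dist = j, dist
        if best >= 0:
            out[i] = best
        elif any(float(np.linalg.norm(c - ctr)) < d / 2.0 for ctr, d in exc_boxes):
            out[i] = -2
    return out


def _confidence(c: Candidate, key: str) -> float:
    if key == "score":
        return c.score if c.score is not None else c.probability
    return c.probability


def froc_curve(candidates_by_scan: dict[str, list[Candidate]],
               annotations_by_scan: dict[str, list],
               excluded_by_scan: dict[str, list] | None = None,
               key: str = "probability") -> FROCCurve:
    """Threshold sweep over candidate confidences."""
    n_scans = len(annotations_by_scan)
    n_annotations = sum(len(v) for v in annotations_by_scan.values())
    if n_annotations == 0:
        raise ValueError("froc_curve needs at least one annotation")
    excluded_by_scan = excluded_by_scan or {}

    conf, ann_id, n_ann_seen = [], [], 0
    for scan, anns in annotations_by_scan.items():
        cands = candidates_by_scan.get(scan, [])
        attr = _attribute_candidates(cands, anns,
                                     excluded_by_scan.get(scan, []))
        for c, a in zip(cands, attr):
            conf.append(_confidence(c, key))
            ann_id.append(a + n_ann_seen if a >= 0 else a)
        n_ann_seen += len(anns)
    conf = np.asarray(conf)
    ann_id = np.asarray(ann_id, dtype=int)

    thresholds = np.unique(conf)[::-1]
    fps_list, sens_list = [0.0], [0.0]  # the empty operating point
    for t in thresholds:
        alive = conf >= t
        hit_ids = np.unique(ann_id[alive & (ann_id >= 0)])
        n_fp = int(np.sum(alive & (ann_id == -1)))
        fps_list.append(n_fp / n_scans)
        sens_list.append(hit_ids.size / n_annotations)
    fps = np.asarray(fps_list)
    sens = np.asarray(sens_list)
    order = np.argsort(fps, kind="stable")
    fps, sens = fps[order], np.maximum.accumulate(sens[order])

    seven = {}
    for target in CPM_FPS_POINTS:
        ok = fps <= target
        seven[target] = float(sens[ok].max()) if ok.any() else 0.0
    return FROCCurve(fps_per_scan=fps, sensitivity=sens, seven_points=seven)


def cpm(seven_sensitivities) -> float:
    """Arithmetic mean of the seven FROC sensitivities (same scale in
    as out; the convention is percent to two decimals)."""
    vals = np.asarray(seven_sensitivities, float)
    if vals.shape != (7,):
        raise ValueError("CPM needs exactly seven sensitivities")
    return float(vals.mean())


def cad_performance(candidates_by_scan: dict[str, list[Candidate]],
                    annotations_by_scan: dict[str, list],
                    excluded_by_scan: dict[str, list] | None = None
                    ) -> tuple[float, float, float]:
    """(FPs/scan, sensitivity, precision) at the fixed operating point."""
    excluded_by_scan = excluded_by_scan or {}
    n_scans = max(len(annotations_by_scan), 1)
    n_annotations = sum(len(v) for v in annotations_by_scan.values())
    n_hit = n_fp = n_matched = n_total = 0
    for scan, anns in annotations_by_scan.items():
        cands = candidates_by_scan.get(scan, [])
        attr = _attribute_candidates(cands, anns,
                                     excluded_by_scan.get(scan, []))
        n_hit += np.unique(attr[attr >= 0]).size
        n_fp += int(np.sum(attr == -1))
        n_matched += int(np.sum(attr >= 0))
        n_total += int(np.sum(attr != -2))
    sensitivity = n_hit / n_annotations if n_annotations else 0.0
    precision = n_matched / n_total if n_total else 0.0
    return n_fp / n_scans, sensitivity, precision


def size_stratified(candidates_by_scan: dict[str, list[Candidate]],
                    annotations_by_scan: dict[str, list],
                    bins: dict[str, tuple[float, float]] = SIZE_BINS
                    ) -> dict[str, dict[str, float]]:
    """Sensitivity and precision within half-open diameter bins; empty
    bins are reported as absent."""
    report: dict[str, dict[str, float]] = {}
    for name, (lo, hi) in bins.items():
        n_ann = n_hit = n_tp_cand = n_fp_cand = 0
        for scan, anns in annotations_by_scan.items():
            cands = candidates_by_scan.get(scan, [])
            attr = _attribute_candidates(cands, anns, [])
            in_bin = [j for j, a in enumerate(anns)
                      if lo <= _ann_box(a)[1] < hi]
            n_ann += len(in_bin)
            hit = np.unique(attr[attr >= 0])
            n_hit += sum(1 for j in in_bin if j in hit)
            n_tp_cand += int(np.sum(np.isin(attr, in_bin) & (attr >= 0)))
            n_fp_cand += int(np.sum((attr == -1)
                                    & np.asarray([lo <= c.diameter < hi
                                                  for c in cands], bool)))
        if n_ann == 0:
            continue
        denom = n_tp_cand + n_fp_cand
        report[name] = {
            "n_annotations": n_ann,
            "sensitivity": n_hit / n_ann,
            "precision": (n_tp_cand / denom) if denom else 0.0,
        }
    return report


def t_critical(k: int, alpha: float = 0.05) -> float:
    """Two-sided critical value of t(k-1) at significance ``alpha``."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, k - 1))


def paired_t(precisions_a, precisions_b, alpha: float = 0.05
             ) -> tuple[float, bool]:
    """Paired t statistic tau = |sqrt(k) * mean(delta) / sd(delta)| and
    its significance against the two-sided critical value."""
    a = np.asarray(precisions_a, float)
    b = np.asarray(precisions_b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with k >= 2")
    delta = a - b
    k = delta.size
    sd = float(delta.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate paired t-test: zero variance of differences")
    tau = abs(np.sqrt(k) * float(delta.mean()) / sd)
    return tau, tau >= t_critical(k, alpha)
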