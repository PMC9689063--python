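"""FROC/CPM, CAD performance, size strata, paired t-test."""

import numpy as np
import pytest

from nodulecad.core import Candidate, NoduleAnnotation
from nodulecad.evaluation import (cad_performance, cpm, froc_curve, hit_test,
                                  paired_t, size_stratified, t_critical)

# printed seven-point FROC rows reused as arithmetic fixtures
TSND_ROW = (77.08, 84.90, 90.48, 94.04, 95.70, 95.97, 95.97)
NNET_ROW = (59.38, 72.66, 78.13, 84.38, 87.50, 89.06, 89.84)
SCPM_ROW = (74.30, 82.90, 88.90, 92.20, 93.90, 95.80, 96.40)
DEEPSEED_ROW = (73.90, 80.30, 85.80, 88.80, 90.70, 91.60, 92.00)


def cand(z, y, x, p, d=5.0, scan="s"):
    return Candidate(center=(z, y, x), diameter=d, probability=p, scan_id=scan)


def ann(z, y, x, d):
    return np.array([z, y, x, d], float)


class TestHitTest:
    def test_coincident_centers(self):
        assert hit_test(cand(1, 2, 3, 0.5), ann(1, 2, 3, 6))

    def test_distance_equal_diameter_misses(self):
        assert not hit_test(cand(0, 0, 8, 0.5), ann(0, 0, 0, 8))

    def test_distance_just_inside_radius(self):
        assert hit_test(cand(0, 0, 0.49 * 8, 0.5), ann(0, 0, 0, 8))
        assert not hit_test(cand(0, 0, 0.5 * 8, 0.5), ann(0, 0, 0, 8))

    def test_accepts_annotation_objects(self):
        a = NoduleAnnotation("s", (1.0, 2.0, 3.0), 6.0, unit="voxel")
        assert hit_test(cand(1, 2, 3, 0.5), a)


def brute_force_froc(cands_by_scan, anns_by_scan):
    """Independent oracle: enumerate every threshold with python loops."""
    thresholds = sorted({c.probability for v in cands_by_scan.values()
                         for c in v}, reverse=True)
    n_scans = len(anns_by_scan)
    n_ann = sum(len(v) for v in anns_by_scan.values())
    points = [(0.0, 0.0)]
    for t in thresholds:
        hit, fp = 0, 0
        for scan, anns in anns_by_scan.items():
            alive = [c for c in cands_by_scan.get(scan, [])
                     if c.probability >= t]
            matched = set()
            for c in alive:
                dists = [(np.linalg.norm(np.asarray(c.center)
                                         - np.asarray(a[:3])), j)
                         for j, a in enumerate(anns)]
                covering = [(d, j) for d, j in dists if d < anns[j][3] / 2]
                if covering:
                    matched.add(min(covering)[1])
                else:
                    fp += 1
            hit += len(matched)
        points.append((fp / n_scans, hit / n_ann))
    return points


class TestFROC:
    def test_perfect_detector(self):
        anns = {"a": [ann(10, 10, 10, 8)], "b": [ann(20, 20, 20, 10)]}
        cands = {"a": [cand(10, 10, 10, 0.9, scan="a")],
                 "b": [cand(20, 20, 21, 0.8, scan="b")]}
        curve = froc_curve(cands, anns)
        assert curve.seven_points[0.125] == 1.0
        assert curve.cpm == 1.0

    def test_two_scan_worked_example(self):
        """scan1: TP p=.9 + FP p=.8; scan2: FP p=.7 -> at <=0.5 FPs/scan
        the achievable sensitivity is 0.5."""
        anns = {"s1": [ann(10, 10, 10, 8)], "s2": [ann(30, 30, 30, 8)]}
        cands = {"s1": [cand(10, 10, 10, 0.9, scan="s1"),
                        cand(50, 50, 50, 0.8, scan="s1")],
                 "s2": [cand(50, 10, 10, 0.7, scan="s2")]}
        curve = froc_curve(cands, anns)
        assert curve.seven_points[0.5] == pytest.approx(0.5)
        assert curve.seven_points[0.25] == pytest.approx(0.5)

    def test_duplicate_tp_candidate_changes_nothing(self):
        anns = {"s": [ann(10, 10, 10, 8)]}
        base = {"s": [cand(10, 10, 10, 0.9), cand(40, 40, 40, 0.3)]}
        dup = {"s": base["s"] + [cand(10, 11, 10, 0.85)]}
        c1, c2 = froc_curve(base, anns), froc_curve(dup, anns)
        assert c1.seven_points == c2.seven_points

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            anns = {f"s{i}": [ann(*rng.uniform(5, 45, 3), rng.uniform(5, 10))
                              for _ in range(rng.integers(1, 3))]
                    for i in range(3)}
            cands = {f"s{i}": [cand(*rng.uniform(0, 50, 3), rng.random(),
                                    scan=f"s{i}")
                               for _ in range(rng.integers(0, 7))]
                     for i in range(3)}
            curve = froc_curve(cands, anns)
            oracle = brute_force_froc(cands, anns)
            for fps, sens in oracle:
                for target in (0.125, 0.25, 0.5, 1, 2, 4, 8):
                    if fps <= target:
                        assert curve.seven_points[target] >= sens - 1e-12

    def test_excluded_hits_are_neither_tp_nor_fp(self):
        anns = {"s": [ann(10, 10, 10, 8)]}
        cands = {"s": [cand(10, 10, 10, 0.9), cand(30, 30, 30, 0.95)]}
        excl = {"s": [ann(30, 30, 30, 8)]}
        # without the excluded list the higher-confidence FP would push
        # the low-FP operating points to zero sensitivity
        assert froc_curve(cands, anns).seven_points[0.125] == 0.0
        curve = froc_curve(cands, anns, excluded_by_scan=excl)
        assert curve.seven_points[0.125] == 1.0

    def test_no_annotations_rejected(self):
        with pytest.raises(ValueError):
            froc_curve({"s": []}, {"s": []})


class TestCPM:
    @pytest.mark.parametrize("row,expected", [
        (TSND_ROW, 90.59), (NNET_ROW, 80.14),
        (SCPM_ROW, 89.20), (DEEPSEED_ROW, 86.16),
    ])
    def test_printed_rows(self, row, expected):
        assert round(cpm(row), 2) == expected

    def test_all_zero(self):
        assert cpm([0] * 7) == 0.0

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            cpm([1, 2, 3])


class TestCadPerformance:
    def test_perfect_detector(self):
        anns = {"s": [ann(10, 10, 10, 8)]}
        cands = {"s": [cand(10, 10, 10, 0.9)]}
        assert cad_performance(cands, anns) == (0.0, 1.0, 1.0)

    def test_one_tp_three_fp(self):
        anns = {"s": [ann(10, 10, 10, 8)]}
        cands = {"s": [cand(10, 10, 10, 0.9), cand(30, 30, 30, 0.8),
                       cand(40, 40, 40, 0.7), cand(20, 40, 20, 0.6)]}
        fps, sens, prec = cad_performance(cands, anns)
        assert (fps, sens, prec) == (3.0, 1.0, 0.25)

    def test_removing_fp_increases_precision(self):
        anns = {"s": [ann(10, 10, 10, 8)]}
        full = [cand(10, 10, 10, 0.9), cand(30, 30, 30, 0.8),
                cand(40, 40, 40, 0.7)]
        _, _, p1 = cad_performance({"s": full}, anns)
        _, _, p2 = cad_performance({"s": full[:-1]}, anns)
        assert p2 > p1


class TestSizeStratified:
    def test_bin_edges_half_open(self):
        anns = {"s": [ann(10, 10, 10, 10.0)]}  # d=10 -> medium
        cands = {"s": [cand(10, 10, 10, 0.9, d=10.0)]}
        report = size_stratified(cands, anns)
        assert "medium" in report and "small" not in report
        assert report["medium"]["sensitivity"] == 1.0

    def test_empty_bins_absent(self):
        anns = {"s": [ann(10, 10, 10, 5.0), ann(30, 30, 30, 8.0)]}
        report = size_stratified({"s": []}, anns)
        assert set(report) == {"small"}

    def test_bin_weighted_sensitivity_is_conserved(self, rng):
        anns = {"s": [ann(*rng.uniform(10, 90, 3), d)
                      for d in (4, 7, 12, 18, 25)]}
        cands = {"s": [cand(*a[:3], 0.9, d=a[3]) for a in anns["s"][:3]]}
        report = size_stratified(cands, anns)
        total = sum(r["n_annotations"] * r["sensitivity"]
                    for r in report.values())
        n = sum(r["n_annotations"] for r in report.values())
        _, overall, _ = cad_performance(cands, anns)
        assert total / n == pytest.approx(overall)


class TestPairedT:
    def test_hand_computed_fixture(self):
        a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], float)
        b = np.zeros(10)
        tau, significant = paired_t(a, b)
        assert tau == pytest.approx(3.0, abs=1e-9)
        assert significant

    def test_critical_value_df9(self):
        assert t_critical(10) == pytest.approx(2.262, abs=5e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t([0.5, 0.5, 0.5], [0.4, 0.4, 0.4])

    def test_negation_symmetry(self, rng):
        a, b = rng.random(8), rng.random(8)
        tau1, _ = paired_t(a, b)
        tau2, _ = paired_t(b, a)
        assert tau1 == pytest.approx(tau2)
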