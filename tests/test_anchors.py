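"""Anchor grid, 3D IoU, label assignment and offset coding."""

import numpy as np
import pytest

from nodulecad.anchors import (assign_labels, build_anchor_grid,
                               decode_offsets, encode_offsets, iou_3d,
                               iou_matrix)


def rasterized_iou(a, b, resolution=4):
    """Independent oracle: voxel-count IoU of two cubes on a fine grid."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    lo = np.minimum(a[:3] - a[3] / 2, b[:3] - b[3] / 2) - 1
    hi = np.maximum(a[:3] + a[3] / 2, b[:3] + b[3] / 2) + 1
    axes = [np.arange(l, h, 1.0 / resolution) + 0.5 / resolution
            for l, h in zip(lo, hi)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)

    def inside(box):
        return ((np.abs(zz - box[0]) < box[3] / 2)
                & (np.abs(yy - box[1]) < box[3] / 2)
                & (np.abs(xx - box[2]) < box[3] / 2))

    ia, ib = inside(a), inside(b)
    union = (ia | ib).sum()
    return (ia & ib).sum() / union


class TestAnchorGrid:
    @pytest.mark.parametrize("edge,expected", [
        (96, 3 * 24**3 + 2 * 12**3),   # 44,928
        (32, 3 * 8**3 + 2 * 4**3),     # 1,664
        (48, 3 * 12**3 + 2 * 6**3),
    ])
    def test_anchor_count(self, edge, expected):
        grid = build_anchor_grid((edge,) * 3)
        assert grid.n_anchors == expected

    def test_96_patch_count_is_44928(self):
        assert build_anchor_grid((96, 96, 96)).n_anchors == 44928

    def test_centers_inside_patch(self):
        grid = build_anchor_grid((32, 32, 32))
        assert np.all(grid.boxes[:, :3] >= 0)
        assert np.all(grid.boxes[:, :3] < 32)

    def test_diameters_by_scale(self):
        grid = build_anchor_grid((32, 32, 32))
        s2 = grid.boxes[grid.scale_of == 0, 3]
        s3 = grid.boxes[grid.scale_of == 1, 3]
        assert set(s2) == {5.0, 8.0, 11.0}
        assert set(s3) == {15.0, 21.0}

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError):
            build_anchor_grid((30, 32, 32))


class TestIoU:
    def test_identical_boxes(self):
        assert iou_3d((3, 4, 5, 8), (3, 4, 5, 8)) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        assert iou_3d((0, 0, 0, 2), (10, 0, 0, 2)) == 0.0

    def test_shifted_cubes_third(self):
        assert iou_3d((0, 0, 0, 2), (1, 0, 0, 2)) == pytest.approx(1 / 3)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            a = np.append(rng.uniform(0, 10, 3), rng.uniform(1, 8))
            b = np.append(rng.uniform(0, 10, 3), rng.uniform(1, 8))
            ab, ba = iou_3d(a, b), iou_3d(b, a)
            assert ab == pytest.approx(ba)
            assert 0.0 <= ab <= 1.0

    def test_against_rasterization_oracle(self, rng):
        """Closed-form IoU within 2% of a fine-grid voxel count on
        integer-coordinate cubes."""
        for _ in range(25):
            a = np.append(rng.integers(0, 8, 3), rng.integers(2, 7)).astype(float)
            b = np.append(rng.integers(0, 8, 3), rng.integers(2, 7)).astype(float)
            expected = rasterized_iou(a, b)
            assert iou_3d(a, b) == pytest.approx(expected, abs=0.02)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            iou_3d((0, 0, 0, 0), (0, 0, 0, 2))


class TestAssignLabels:
    def test_coincident_anchor_is_positive(self, rng):
        grid = build_anchor_grid((32, 32, 32))
        # (2 + 4k) centers: pick the anchor center (14,14,14), d=8
        label = np.array([14.0, 14.0, 14.0, 8.0])
        a = assign_labels(grid, [label], rng)
        assert len(a.positives) == 1
        idx = a.positives[0][0]
        np.testing.assert_allclose(grid.boxes[idx], label)
        assert iou_3d(grid.boxes[idx], label) == pytest.approx(1.0)

    def test_low_iou_label_gets_argmax_anchor(self, rng):
        grid = build_anchor_grid((32, 32, 32))
        label = np.array([13.0, 15.0, 17.0, 28.0])  # max IoU < 0.5
        ious = iou_matrix(grid.boxes, label[None])[:, 0]
        assert ious.max() < 0.5
        a = assign_labels(grid, [label], rng)
        assert len(a.positives) == 1
        assert a.positives[0][0] == int(np.argmax(ious))

    def test_no_labels_all_anchors_negative(self, rng):
        grid = build_anchor_grid((32, 32, 32))
        a = assign_labels(grid, [], rng)
        assert len(a.positives) == 0
        assert a.negatives.size == 1664  # fewer than 4000 -> all kept
        assert a.ignored.size == 0

    def test_sets_disjoint_and_deterministic(self, small_phantom, rng):
        grid = build_anchor_grid((48, 48, 48))
        labels = [np.array([20.0, 22.0, 24.0, 9.0]),
                  np.array([36.0, 12.0, 30.0, 14.0])]
        a1 = assign_labels(grid, labels, np.random.default_rng(5))
        a2 = assign_labels(grid, labels, np.random.default_rng(5))
        np.testing.assert_array_equal(a1.negatives, a2.negatives)
        assert a1.positive_indices.tolist() == a2.positive_indices.tolist()
        all_idx = np.concatenate([a1.positive_indices, a1.negatives, a1.ignored])
        assert len(np.unique(all_idx)) == len(all_idx)

    def test_negatives_respect_iou_ceiling(self, rng):
        grid = build_anchor_grid((32, 32, 32))
        label = np.array([16.0, 16.0, 16.0, 10.0])
        a = assign_labels(grid, [label], rng)
        assert a.negatives.size == 1664 - a.ignored.size - 1
        ious = iou_matrix(grid.boxes[a.negatives], label[None])[:, 0]
        assert np.all(ious <= 0.02)


class TestOffsets:
    def test_identity(self):
        box = np.array([10.0, 12.0, 14.0, 8.0])
        np.testing.assert_allclose(encode_offsets(box, box), 0.0)

    def test_worked_example(self):
        g = np.array([48.0, 46.0, 46.0, 16.0])
        b = np.array([46.0, 46.0, 46.0, 8.0])
        r = encode_offsets(g, b)
        np.testing.assert_allclose(r, [0.25, 0.0, 0.0, np.log(2.0)], atol=1e-12)

    def test_roundtrip_100_random_pairs(self, rng):
        for _ in range(100):
            g = np.append(rng.uniform(0, 96, 3), rng.uniform(3, 30))
            b = np.append(rng.uniform(0, 96, 3), rng.uniform(3, 30))
            np.testing.assert_allclose(decode_offsets(encode_offsets(g, b), b),
                                       g, rtol=1e-12, atol=1e-9)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            encode_offsets((0, 0, 0, -1.0), (0, 0, 0, 8.0))
        with pytest.raises(ValueError):
            decode_offsets((0, 0, 0, 0), (0, 0, 0, 0.0))
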