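"""MSFE/MSFD-Net/CS-Net contracts: shapes, ordering, parameter counts."""

import numpy as np
import pytest

from nodulecad import nn
from nodulecad.networks import (CSNet, DetectorConfig, MSFE, MSFEConfig,
                                MSFDNet, ScorerConfig, count_parameters,
                                default_detector_config,
                                default_scorer_config, load_checkpoint,
                                save_checkpoint)

TINY = MSFEConfig(encoder_widths=(4, 6, 8, 8, 8), blocks_per_layer=(1, 1, 1, 1),
                  decoder_width=8, dropout_p=0.0)


@pytest.fixture(scope="module")
def tiny_detector():
    return MSFDNet(DetectorConfig(msfe=TINY, head_width=8), seed=0)


@pytest.fixture(scope="module")
def tiny_scorer():
    return CSNet(ScorerConfig(msfe=TINY, agg_channels=128, hidden=16), seed=0)


class TestMSFE:
    @pytest.mark.parametrize("edge", [16, 32])
    def test_scale_contract(self, edge):
        msfe = MSFE(TINY, np.random.default_rng(0)).eval()
        s2, s3 = msfe(np.zeros((1, 1, edge, edge, edge), np.float32))
        assert s2.shape[2:] == (edge // 4,) * 3
        assert s3.shape[2:] == (edge // 8,) * 3

    def test_indivisible_input_rejected(self):
        msfe = MSFE(TINY, np.random.default_rng(0)).eval()
        with pytest.raises(ValueError):
            msfe(np.zeros((1, 1, 20, 16, 16), np.float32))

    def test_inference_deterministic(self):
        msfe = MSFE(MSFEConfig(encoder_widths=(4, 6, 8, 8, 8),
                               blocks_per_layer=(1, 1, 1, 1), decoder_width=8,
                               dropout_p=0.5),
                    np.random.default_rng(0)).eval()
        x = np.random.default_rng(1).random((1, 1, 16, 16, 16), dtype=np.float32)
        s2a, _ = msfe(x)
        s2b, _ = msfe(x)
        np.testing.assert_array_equal(s2a.data, s2b.data)

    def test_se_gate_in_unit_interval(self):
        from nodulecad.networks import ResSEBlock
        block = ResSEBlock(4, 4, np.random.default_rng(0)).eval()
        h = nn.Tensor(np.random.default_rng(2)
                      .standard_normal((2, 4, 4, 4, 4)).astype(np.float32))
        gate = block.se_gate(h).data
        assert np.all(gate > 0) and np.all(gate < 1)

    def test_disabled_se_gate_recovers_plain_residual(self):
        from nodulecad.networks import ResSEBlock
        rng_a = np.random.default_rng(0)
        block = ResSEBlock(4, 4, rng_a, se_enabled=False).eval()
        x = np.random.default_rng(3).random((1, 4, 4, 4, 4), dtype=np.float32)
        out = block(x).data
        # manual plain residual path with the same weights
        h = nn.relu(block.bn1(block.conv1(nn.Tensor(x))))
        h = block.bn2(block.conv2(h))
        expected = nn.relu(h + nn.Tensor(x)).data
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestMSFDNet:
    def test_output_rows_match_anchor_count(self, tiny_detector):
        cls, reg = tiny_detector.eval()(np.zeros((1, 1, 32, 32, 32), np.float32))
        assert cls.shape == (1, 1664, 1)
        assert reg.shape == (1, 1664, 4)

    def test_batch_equivariance(self, tiny_detector):
        rng = np.random.default_rng(0)
        a = rng.random((1, 1, 16, 16, 16), dtype=np.float32)
        b = rng.random((1, 1, 16, 16, 16), dtype=np.float32)
        det = tiny_detector.eval()
        cls_ab, _ = det(np.concatenate([a, b]))
        cls_ba, _ = det(np.concatenate([b, a]))
        np.testing.assert_allclose(cls_ab.data[0], cls_ba.data[1], atol=2e-4)
        np.testing.assert_allclose(cls_ab.data[1], cls_ba.data[0], atol=2e-4)

    def test_head_order_matches_anchor_grid(self, tiny_detector):
        """A localized input bump must move the most-responsive anchors
        to its location under the grid's flat ordering."""
        from nodulecad.anchors import build_anchor_grid
        grid = build_anchor_grid((32, 32, 32))
        det = tiny_detector.eval()
        base = np.full((1, 1, 32, 32, 32), 0.3, np.float32)
        bumped = base.copy()
        bumped[0, 0, 6:12, 20:26, 6:12] = 1.0
        d = np.abs(det(bumped)[0].data - det(base)[0].data).reshape(-1)
        top = grid.boxes[np.argsort(-d)[:10], :3]
        center = np.array([9.0, 23.0, 9.0])
        assert np.median(np.linalg.norm(top - center, axis=1)) < 12.0

    def test_gradient_reaches_every_parameter(self):
        det = MSFDNet(DetectorConfig(msfe=TINY, head_width=8), seed=1)
        det.train()
        cls, reg = det(np.random.default_rng(0)
                       .random((1, 1, 16, 16, 16), dtype=np.float32))
        probs = nn.sigmoid(cls.reshape(-1))
        loss = (nn.gather(probs, np.array([0])) * (-1.0)
                + nn.gather(probs, np.array([100]))).sum() \
            + (reg.reshape(-1, 4) ** 2).sum() * 1e-3
        loss.backward()
        missing = [n for n, p in det.named_parameters() if p.grad is None]
        assert missing == []


class TestCSNet:
    def test_score_in_unit_interval(self, tiny_scorer):
        score = tiny_scorer.eval()(np.random.default_rng(0)
                                   .random((2, 1, 32, 32, 32), dtype=np.float32))
        assert score.shape == (2, 1)
        assert np.all(score.data > 0) and np.all(score.data < 1)

    def test_feature_vector_length_256(self, tiny_scorer):
        feats = tiny_scorer.eval().features(
            np.zeros((1, 1, 32, 32, 32), np.float32))
        assert feats.shape == (1, 256)

    def test_wrong_patch_shape_rejected(self, tiny_scorer):
        with pytest.raises(ValueError):
            tiny_scorer(np.zeros((1, 1, 16, 16, 16), np.float32))


class TestParameterCount:
    def test_single_conv_closed_form(self):
        conv = nn.Conv3d(1, 8, 3, np.random.default_rng(0), bias=True)
        total = sum(p.size for p in conv.parameters())
        assert total == 8 * 27 + 8  # 224

    def test_default_detector_near_3_30_million(self):
        n = count_parameters(default_detector_config())
        assert abs(n - 3.30e6) / 3.30e6 < 0.05

    def test_default_scorer_near_1_52_million(self):
        n = count_parameters(default_scorer_config())
        assert abs(n - 1.52e6) / 1.52e6 < 0.05

    def test_model_and_config_counts_agree(self, tiny_detector):
        assert count_parameters(tiny_detector) == \
            count_parameters(DetectorConfig(msfe=TINY, head_width=8))


def test_checkpoint_roundtrip(tmp_path, tiny_detector):
    path = tmp_path / "det.npz"
    save_checkpoint(tiny_detector, path)
    back = load_checkpoint(path)
    assert isinstance(back, MSFDNet)
    assert back.config == tiny_detector.config
    x = np.random.default_rng(5).random((1, 1, 16, 16, 16), dtype=np.float32)
    cls_a, _ = tiny_detector.eval()(x)
    cls_b, _ = back.eval()(x)
    np.testing.assert_allclose(cls_a.data, cls_b.data, atol=1e-6)
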