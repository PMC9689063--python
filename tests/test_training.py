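"""Training machinery: load frequency, patch sampling, schedules, loops."""

import numpy as np
import pytest

from nodulecad.core import CTVolume
from nodulecad.fpr import CandidatePatch
from nodulecad.networks import (CSNet, DetectorConfig, MSFDNet, MSFEConfig,
                                ScorerConfig)
from nodulecad.training import (DetectorDataset, TrainConfig, load_frequency,
                                lr_at_epoch, sample_training_patch,
                                score_auc, train_detector, train_scorer)

TINY = MSFEConfig(encoder_widths=(4, 6, 8, 8, 8), blocks_per_layer=(1, 1, 1, 1),
                  decoder_width=8, dropout_p=0.0)


class TestLoadFrequency:
    @pytest.mark.parametrize("d,expected", [
        (10.0, 4), (3.0, 1), (30.0, 10), (9.9, 3), (6.7, 3),
    ])
    def test_values(self, d, expected):
        assert load_frequency(d) == expected

    def test_monotone_on_range(self):
        d = np.linspace(3, 30, 200)
        lf = [load_frequency(x) for x in d]
        assert all(b >= a for a, b in zip(lf, lf[1:]))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            load_frequency(0.0)

    def test_epoch_pool_honors_load_frequency(self, rng):
        """A 20 mm nodule appears 7 times per epoch, a 10 mm one 4."""
        pre = CTVolume(np.full((64, 64, 64), 57, np.uint8))
        boxes = [np.array([20.0, 20, 20, 20.0]), np.array([40.0, 40, 40, 10.0])]
        ds = DetectorDataset([(pre, boxes)], patch_shape=(48, 48, 48),
                             augment=False)
        samples = ds.sample_epoch(rng)
        # count appearances via the target diameters present in each patch
        d20 = sum(1 for _, bx in samples if any(b[3] == 20.0 for b in bx))
        d10 = sum(1 for _, bx in samples if any(b[3] == 10.0 for b in bx))
        assert len(samples) == 7 + 4
        assert d20 >= 7 and d10 >= 4  # >= because crops can contain both


class TestSampleTrainingPatch:
    def _pre(self, rng):
        grid = rng.integers(0, 255, (80, 80, 80)).astype(np.uint8)
        return CTVolume(grid)

    def test_target_nodule_always_inside(self, rng):
        pre = self._pre(rng)
        target = np.array([40.0, 40.0, 40.0, 10.0])
        for _ in range(20):
            _, boxes = sample_training_patch(pre, target, rng, (48, 48, 48))
            assert len(boxes) >= 1
            b = boxes[0]
            assert np.all(b[:3] >= b[3] / 2 - 1.0)
            assert np.all(b[:3] <= 48 - b[3] / 2 + 1.0)

    def test_identity_augmentation_is_plain_crop(self, rng):
        pre = self._pre(rng)
        target = np.array([40.0, 40.0, 40.0, 10.0])
        rng1 = np.random.default_rng(9)
        patch, boxes = sample_training_patch(pre, target, rng1, (48, 48, 48),
                                             augment=False)
        lo = np.round(target[:3] - boxes[0][:3]).astype(int)
        np.testing.assert_array_equal(
            patch, pre.grid[lo[0]:lo[0] + 48, lo[1]:lo[1] + 48,
                            lo[2]:lo[2] + 48])

    def test_seeded_reproducibility(self, rng):
        pre = self._pre(rng)
        target = np.array([30.0, 50.0, 40.0, 8.0])
        p1, b1 = sample_training_patch(pre, target,
                                       np.random.default_rng(3), (48,) * 3)
        p2, b2 = sample_training_patch(pre, target,
                                       np.random.default_rng(3), (48,) * 3)
        p3, _ = sample_training_patch(pre, target,
                                      np.random.default_rng(4), (48,) * 3)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(np.stack(b1), np.stack(b2))
        assert not np.array_equal(p1, p3)

    def test_border_padding_uses_fill_gray(self, rng):
        pre = CTVolume(np.zeros((40, 40, 40), np.uint8))
        target = np.array([2.0, 2.0, 2.0, 6.0])
        patch, _ = sample_training_patch(pre, target,
                                         np.random.default_rng(0), (48,) * 3,
                                         augment=False)
        assert np.sum(patch == 170) > 0


class TestSchedule:
    def test_default_schedule_values(self):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, 1) == pytest.approx(1e-3)
        assert lr_at_epoch(cfg, 60) == pytest.approx(1e-3)
        assert lr_at_epoch(cfg, 61) == pytest.approx(1e-4)
        assert lr_at_epoch(cfg, 121) == pytest.approx(5e-5)
        assert lr_at_epoch(cfg, 181) == pytest.approx(1e-5)
        assert lr_at_epoch(cfg, 300) == pytest.approx(1e-5)

    def test_invalid_milestones_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_milestones=((60, 0.1), (30, 0.5)))
        with pytest.raises(ValueError):
            TrainConfig(lr_milestones=((60, 1.5),))


class TestTrainDetector:
    def _dataset(self, rng):
        grid = np.full((64, 64, 64), 57, np.uint8)
        grid[28:36, 28:36, 28:36] = 175
        pre = CTVolume(grid)
        boxes = [np.array([31.5, 31.5, 31.5, 8.0])]
        return DetectorDataset([(pre, boxes)], patch_shape=(32, 32, 32),
                               patches_per_epoch=2)

    def test_smoke_run_losses_finite(self, rng):
        ds = self._dataset(rng)
        model = MSFDNet(DetectorConfig(msfe=TINY, head_width=8), seed=0)
        cfg = TrainConfig(batch_size=2, epochs=2, lr_initial=1e-3,
                          lr_milestones=(), beta_ohnm=10.0, seed=0)
        model, log = train_detector(ds, model, cfg)
        assert len(log) == 2
        assert all(np.isfinite(r.total_loss) and r.total_loss >= 0 for r in log)

    def test_loss_decreases_on_fixed_task(self, rng):
        ds = self._dataset(rng)
        ds.augment = False
        model = MSFDNet(DetectorConfig(msfe=TINY, head_width=8), seed=1)
        cfg = TrainConfig(batch_size=2, epochs=8, lr_initial=3e-3,
                          lr_milestones=(), beta_ohnm=10.0, seed=1)
        model, log = train_detector(ds, model, cfg)
        assert np.mean([r.total_loss for r in log[-2:]]) < \
            np.mean([r.total_loss for r in log[:2]])


class TestTrainScorer:
    def _patches(self, rng, n_pos=12, n_neg=24):
        out = []
        for i in range(n_pos + n_neg):
            grid = rng.normal(57, 5, (32, 32, 32))
            label = 1 if i < n_pos else 0
            if label:
                zz, yy, xx = np.ogrid[:32, :32, :32]
                ball = (zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 36
                grid[ball] = 175
            out.append(CandidatePatch(
                grid=np.clip(grid, 0, 255).astype(np.uint8), label=label))
        return out

    def test_negative_resampling_rule(self, rng):
        patches = self._patches(rng)
        captured = []
        model = CSNet(ScorerConfig(msfe=TINY, agg_channels=16, hidden=8),
                      seed=0)
        cfg = TrainConfig(batch_size=100, epochs=1, lr_initial=1e-3,
                          lr_milestones=(), beta_ohnm=5.0, seed=0,
                          neg_resample_fraction=0.7)
        # run one epoch; floor(0.7*24)=16 negatives + 12 positives
        model, log = train_scorer(patches, model, cfg)
        assert len(log) == 1

    def test_learns_separable_patches(self, rng):
        patches = self._patches(rng, n_pos=16, n_neg=32)
        model = CSNet(ScorerConfig(msfe=TINY, agg_channels=16, hidden=8),
                      seed=0)
        cfg = TrainConfig(batch_size=24, epochs=6, lr_initial=3e-3,
                          lr_milestones=(), beta_ohnm=5.0, seed=0)
        model, _ = train_scorer(patches, model, cfg)
        assert score_auc(model, patches) > 0.9
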