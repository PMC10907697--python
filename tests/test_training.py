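"""Loss, augmentation consistency, LR schedule and reproducible training."""

import numpy as np
import pytest

from softceph.heatmap_codec import GaussianConfig, HeatmapStack, decode, encode
from softceph.model import ModelConfig, build_bhrnet
from softceph.schema import LandmarkSet, load_schema
from softceph.training import (AugmentConfig, PlateauScheduler, TrainConfig,
                               augment, heatmap_mse_loss, train)


class TestLoss:
    def test_identical_stacks_zero(self):
        v = np.random.default_rng(0).uniform(0, 1, (3, 16, 16))
        a = HeatmapStack(v.copy(), 4)
        assert heatmap_mse_loss(a, HeatmapStack(v.copy(), 4)) == 0.0

    def test_constant_offset_closed_form(self):
        zeros = HeatmapStack(np.zeros((2, 8, 8)), 4)
        halves = HeatmapStack(np.full((2, 8, 8), 0.5), 4)
        assert heatmap_mse_loss(halves, zeros) == pytest.approx(0.25)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = HeatmapStack(rng.uniform(0, 1, (2, 8, 8)), 4)
        b = HeatmapStack(rng.uniform(0, 1, (2, 8, 8)), 4)
        assert heatmap_mse_loss(a, b) == pytest.approx(heatmap_mse_loss(b, a))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            heatmap_mse_loss(HeatmapStack(np.zeros((2, 8, 8)), 4),
                             HeatmapStack(np.zeros((3, 8, 8)), 4))


class TestScheduler:
    def test_flat_history_triggers_single_tenfold_cut(self):
        sched = PlateauScheduler(1e-3, patience=20, factor=0.1)
        lrs = [sched.step(0.5) for _ in range(21)]
        assert lrs[:-1] == [1e-3] * 20
        assert lrs[-1] == pytest.approx(1e-4)

    def test_improvement_resets_patience(self):
        sched = PlateauScheduler(1e-3, patience=3, factor=0.1)
        for loss in (1.0, 0.9, 0.95, 0.95, 0.8, 0.85, 0.85):
            lr = sched.step(loss)
        assert lr == 1e-3  # never 3 consecutive stale epochs


class TestAugment:
    def test_mirror_flip_arithmetic_and_pair_swap(self):
        schema = load_schema()
        img = np.zeros((256, 256, 3), dtype=np.uint8)
        pts = np.zeros((34, 2))
        pts[schema.index("ExL")] = (200.0, 80.0)
        pts[schema.index("ExR")] = (60.0, 80.0)
        lm = LandmarkSet(pts)
        cfg = AugmentConfig(rotation_range=0.0, mirror_prob=1.0,
                            grayscale_prob=0.0, hsv_jitter=(0, 0, 0))
        _, out = augment(img, lm, cfg, np.random.default_rng(0), schema)
        # after the flip the ExR slot holds the mirrored ExL x-coordinate
        assert out.points[schema.index("ExR")][0] == pytest.approx(255 - 200)
        assert out.points[schema.index("ExL")][0] == pytest.approx(255 - 60)

    def test_zero_rotation_identity(self):
        img = np.random.default_rng(0).integers(
            0, 255, (64, 64, 3)).astype(np.uint8)
        pts = np.array([[10.0, 20.0], [40.0, 50.0]])
        cfg = AugmentConfig(rotation_range=0.0, mirror_prob=0.0,
                            grayscale_prob=0.0, hsv_jitter=(0, 0, 0))
        out_img, out = augment(img, LandmarkSet(pts), cfg,
                               np.random.default_rng(1))
        np.testing.assert_allclose(out.points, pts)

    def test_photometric_ops_leave_coordinates(self):
        img = np.random.default_rng(2).integers(
            0, 255, (64, 64, 3)).astype(np.uint8)
        pts = np.array([[10.0, 20.0], [40.0, 50.0]])
        cfg = AugmentConfig(rotation_range=0.0, mirror_prob=0.0,
                            grayscale_prob=1.0)
        out_img, out = augment(img, LandmarkSet(pts), cfg,
                               np.random.default_rng(3))
        np.testing.assert_allclose(out.points, pts)
        # grayscale: all channels equal
        assert (out_img[..., 0] == out_img[..., 1]).all()

    def test_rotation_moves_landmarks_with_image(self):
        # a bright dot rendered at a landmark stays at the landmark
        img = np.zeros((96, 96, 3), dtype=np.uint8)
        img[60:64, 30:34] = 255
        pts = np.array([[31.5, 61.5]])
        cfg = AugmentConfig(rotation_range=25.0, mirror_prob=0.0,
                            grayscale_prob=0.0, hsv_jitter=(0, 0, 0))
        out_img, out = augment(img, LandmarkSet(pts), cfg,
                               np.random.default_rng(7))
        bright = np.argwhere(out_img[..., 0] > 128)
        cy, cx = bright.mean(axis=0)
        assert np.hypot(cx - out.points[0, 0], cy - out.points[0, 1]) < 2.0

    def test_augmented_landmarks_consistent_with_codec(self):
        # re-encoding augmented landmarks and decoding reproduces them
        # within the stride/2 quantization bound
        gcfg = GaussianConfig(32, 128, 2.0)
        img = np.zeros((128, 128, 3), dtype=np.uint8)
        pts = np.array([[30.0, 40.0], [90.0, 100.0], [64.0, 64.0]])
        cfg = AugmentConfig(rotation_range=20.0, mirror_prob=0.5,
                            grayscale_prob=0.5)
        rng = np.random.default_rng(11)
        for _ in range(5):
            _, lm = augment(img, LandmarkSet(pts.copy()), cfg, rng)
            dec, _ = decode(encode(lm, gcfg))
            inb = lm.visible & dec.visible
            err = np.abs(dec.points[inb] - lm.points[inb])
            assert (err <= gcfg.stride / 2 + 1e-9).all()


@pytest.fixture(scope="module")
def micro_dataset(tiny_train_set):
    return tiny_train_set[:20]


class TestTrainLoop:
    def _cfgs(self, epochs=3):
        mcfg = ModelConfig(input_size=128, heatmap_size=32, n_landmarks=8,
                           base_width=8, stage2_repeats=1, stage3_repeats=1)
        tcfg = TrainConfig(max_epochs=epochs, batch_size=4, seed=5)
        return mcfg, tcfg

    def test_best_loss_monotone_nonincreasing(self, micro_dataset):
        mcfg, tcfg = self._cfgs()
        _, hist = train(build_bhrnet(mcfg, seed=5), micro_dataset, tcfg, None)
        best = np.minimum.accumulate([h["loss"] for h in hist])
        assert (np.diff(best) <= 0).all()
        assert len(hist) == tcfg.max_epochs

    def test_same_seed_identical_history(self, micro_dataset):
        mcfg, tcfg = self._cfgs(epochs=2)
        _, h1 = train(build_bhrnet(mcfg, seed=5), micro_dataset, tcfg, None)
        _, h2 = train(build_bhrnet(mcfg, seed=5), micro_dataset, tcfg, None)
        assert [h["loss"] for h in h1] == [h["loss"] for h in h2]

    def test_empty_dataset_raises(self):
        mcfg, tcfg = self._cfgs()
        with pytest.raises(ValueError):
            train(build_bhrnet(mcfg, seed=0), [], tcfg, None)

    def test_offline_expansion_multiplies_samples(self, micro_dataset):
        # 4x expansion -> 4x as many gradient samples per epoch; verify
        # through the augmented-history length being unchanged but the
        # loss averaging over the expanded set (smoke: runs end to end)
        mcfg, tcfg = self._cfgs(epochs=1)
        schema = load_schema()
        acfg = AugmentConfig(rotation_range=10.0, expansion_factor=2)
        _, hist = train(build_bhrnet(mcfg, seed=1), micro_dataset[:4],
                        tcfg, acfg, schema=None)
        assert len(hist) == 1 and np.isfinite(hist[0]["loss"])
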