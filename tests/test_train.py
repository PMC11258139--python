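"""Subtomogram sampling, augmentation, Dice loss, and the training loop."""

import numpy as np
import pytest

from tomopick.io import ParticleSet, Tomogram, normalize_tomogram
from tomopick.labels import LabelVolume, MaskSpec, paint_labels
from tomopick.model import ModelConfig, build_model
from tomopick.simulate import ClassSpec, SceneSpec, simulate_scene
from tomopick.train import (
    TrainConfig, TrainSample, augment_sample, dice_loss, f1_alpha,
    sample_training_subtomograms, train,
)


class _NeverFire:
    """Stub rng whose uniform draws never trigger a p=0.5 transform."""

    def random(self):
        return 0.99


class _FireOnly:
    """Stub rng that fires chosen gate draws (by index in draw order).

    Draw order in augment_sample: mirror gate, then (only if it fired)
    three per-axis gates, then scale gate, rotation gate, elastic gate.
    """

    def __init__(self, fire_indices, uniform_value=None):
        self.fire = set(fire_indices)
        self.i = -1
        self.uniform_value = uniform_value
        self._rng = np.random.default_rng(0)

    def random(self):
        self.i += 1
        return 0.01 if self.i in self.fire else 0.99

    def uniform(self, lo, hi):
        return self.uniform_value if self.uniform_value is not None else (lo + hi) / 2

    def normal(self, *args, **kwargs):
        return self._rng.normal(*args, **kwargs)


def toy_scene(shape=(48, 48, 48), n=6, seed=3, noise=0.0):
    spec = SceneSpec(shape=shape, classes=(ClassSpec(1, "ball", 9.0, 1.0),),
                     n_particles=(n,), min_separation=12.0, noise_sigma=noise,
                     smooth_sigma=1.0, seed=seed)
    scene = simulate_scene(spec)
    labels = paint_labels(shape, scene.truth, {1: MaskSpec("tball", 3, 1)})
    return scene, labels


class TestSampling:
    def test_centered_particle_gets_whole_volume(self):
        tomo = Tomogram(np.arange(64 ** 3, dtype=np.float32).reshape(64, 64, 64))
        labels = LabelVolume(np.ones((64, 64, 64), dtype=np.int16))
        ps = ParticleSet.from_arrays([[32, 32, 32]], 1)
        samples = sample_training_subtomograms(tomo, labels, ps, N=64)
        assert len(samples) == 1
        np.testing.assert_array_equal(samples[0].volume, tomo.data)

    def test_boundary_particle_window_shifted_inward(self):
        tomo = Tomogram(np.zeros((64, 64, 64), dtype=np.float32))
        labels = LabelVolume(np.ones((64, 64, 64), dtype=np.int16))
        ps = ParticleSet.from_arrays([[0, 0, 0]], 1)
        samples = sample_training_subtomograms(tomo, labels, ps, N=32)
        assert samples[0].volume.shape == (32, 32, 32)
        # window is [0:32]^3: mark a voxel to verify
        tomo.data[0, 0, 0] = 5.0
        samples = sample_training_subtomograms(tomo, labels, ps, N=32)
        assert samples[0].volume[0, 0, 0] == 5.0

    def test_one_sample_per_particle_each_contains_its_center(self):
        scene, labels = toy_scene()
        tomo = scene.tomogram
        samples = sample_training_subtomograms(tomo, labels, scene.truth, N=32)
        assert len(samples) == len(scene.truth)
        for sample, rec in zip(samples, scene.truth):
            assert np.any(sample.label > 0)
            # the particle's own center voxel is inside and foreground
            c = np.floor(rec.center + 0.5).astype(int)
            lo = np.clip(c - 16, 0, np.array(scene.tomogram.shape) - 32)
            rel = c - lo
            assert sample.label[tuple(rel)] > 0

    def test_oversized_window_rejected(self):
        tomo = Tomogram(np.zeros((16, 16, 16), dtype=np.float32))
        labels = LabelVolume(np.zeros((16, 16, 16), dtype=np.int16))
        ps = ParticleSet.from_arrays([[8, 8, 8]], 1)
        with pytest.raises(ValueError, match="exceeds"):
            sample_training_subtomograms(tomo, labels, ps, N=32)


class TestAugment:
    @pytest.fixture()
    def ball_sample(self):
        labels = paint_labels((32, 32, 32), ParticleSet.from_arrays([[16, 16, 16]], 1),
                              {1: MaskSpec("ball", 5, 1)})
        vol = (labels.data > 0).astype(np.float32)
        return TrainSample(vol, labels.data.copy())

    def test_no_transform_is_identity(self, ball_sample):
        out = augment_sample(ball_sample, _NeverFire())
        np.testing.assert_array_equal(out.volume, ball_sample.volume)
        np.testing.assert_array_equal(out.label, ball_sample.label)

    def test_mirror_preserves_foreground_count(self, ball_sample):
        out = augment_sample(ball_sample, _FireOnly({0, 1, 3}))  # mirror z only
        assert np.count_nonzero(out.label) == np.count_nonzero(ball_sample.label)
        assert out.volume.shape == ball_sample.volume.shape

    def test_rotation_15deg_count_within_10pct(self, ball_sample):
        # draw 0 = mirror gate (no), 1 = scale gate (no), 2 = rotation gate
        out = augment_sample(ball_sample, _FireOnly({2}, uniform_value=15.0))
        n0 = np.count_nonzero(ball_sample.label)
        n1 = np.count_nonzero(out.label)
        assert abs(n1 - n0) <= 0.1 * n0

    def test_elastic_keeps_shape_and_stays_bounded(self, ball_sample):
        # draw 0 = mirror (no), 1 = scale (no), 2 = rotation (no), 3 = elastic
        out = augment_sample(ball_sample, _FireOnly({3}, uniform_value=0.05))
        assert out.volume.shape == ball_sample.volume.shape
        n0 = np.count_nonzero(ball_sample.label)
        assert abs(np.count_nonzero(out.label) - n0) <= 0.3 * n0

    def test_real_rng_deterministic(self, ball_sample):
        a = augment_sample(ball_sample, np.random.default_rng(9))
        b = augment_sample(ball_sample, np.random.default_rng(9))
        np.testing.assert_array_equal(a.volume, b.volume)
        np.testing.assert_array_equal(a.label, b.label)


class TestDiceLoss:
    def test_exact_one_hot_near_zero(self):
        truth = np.zeros((8, 8, 8), dtype=np.int16)
        truth[2:5, 2:5, 2:5] = 1
        pred = np.stack([(truth == 0), (truth == 1)]).astype(np.float64)
        assert dice_loss(pred, truth) < 1e-6

    def test_all_background_prediction_near_one(self):
        truth = np.zeros((8, 8, 8), dtype=np.int16)
        truth[0, 0, :4] = 1
        m = 4
        pred = np.stack([np.ones_like(truth), np.zeros_like(truth)]).astype(np.float64)
        eps = 1e-8
        assert dice_loss(pred, truth, eps) == pytest.approx(1 - eps / (m + eps))

    def test_matches_direct_summation_oracle(self, rng):
        p = rng.random((3, 4, 4, 4))
        p /= p.sum(axis=0, keepdims=True)
        g = rng.integers(0, 3, size=(4, 4, 4))
        eps = 1e-8
        expected = 0.0
        for c in (1, 2):
            s1 = s2 = s3 = 0.0
            for z in range(4):
                for y in range(4):
                    for x in range(4):
                        pc = p[c, z, y, x]
                        gc = 1.0 if g[z, y, x] == c else 0.0
                        s1 += pc * gc
                        s2 += pc * pc
                        s3 += gc * gc
            expected += 1 - (2 * s1 + eps) / (s2 + s3 + eps)
        expected /= 2
        assert dice_loss(p, g.astype(np.int16), eps) == pytest.approx(expected, abs=1e-10)

    def test_bounded_and_monotone_along_interpolation(self):
        truth = np.zeros((6, 6, 6), dtype=np.int16)
        truth[1:4, 1:4, 1:4] = 1
        right = np.stack([(truth == 0), (truth == 1)]).astype(np.float64)
        wrong = right[::-1]  # swapped classes
        last = None
        for t in np.linspace(0, 1, 7):
            p = (1 - t) * wrong + t * right
            val = dice_loss(p, truth)
            assert 0.0 <= val <= 1.0
            if last is not None:
                assert val < last
            last = val

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 4, 4, 4)), np.zeros((5, 5, 5), dtype=np.int16))


class TestF1Alpha:
    def test_reduces_to_f1_at_alpha_one(self):
        assert f1_alpha(0.8, 0.8, 1.0) == pytest.approx(0.8)

    def test_direct_substitution(self):
        assert f1_alpha(1.0, 0.5, 3.0) == pytest.approx(2 * 0.125 / 1.125)
        assert f1_alpha(1.0, 0.5, 3.0) == pytest.approx(0.2222, abs=1e-4)

    def test_perfect_scores(self):
        for alpha in (1.0, 2.0, 3.0, 7.5):
            assert f1_alpha(1.0, 1.0, alpha) == 1.0

    def test_zero_denominator_convention(self):
        assert f1_alpha(0.0, 0.0, 3.0) == 0.0

    def test_emphasizes_recall(self):
        low_r = f1_alpha(0.9, 0.5, 3.0)
        high_r = f1_alpha(0.5, 0.9, 3.0)
        assert high_r > low_r

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            f1_alpha(1.2, 0.5, 3.0)


class TestTrainLoop:
    def test_loss_decreases_on_noiseless_scene(self):
        scene, labels = toy_scene(shape=(64, 64, 64), n=10, seed=4)
        tomo = normalize_tomogram(scene.tomogram)
        model = build_model(ModelConfig(n_classes=2, base_channels=8, seed=0))
        cfg = TrainConfig(N=32, epochs=5, batch_size=4, augment=False, seed=0)
        result = train(model, [(tomo, labels, scene.truth)], cfg)
        losses = [row["loss"] for row in result.history]
        assert losses[4] <= losses[0]
        assert all(np.isfinite(losses))

    def test_best_checkpoint_restored_and_reproducible(self):
        scene, labels = toy_scene(shape=(48, 48, 48), n=5, seed=5)
        vscene, _ = toy_scene(shape=(48, 48, 48), n=4, seed=6)
        tomo = normalize_tomogram(scene.tomogram)
        vtomo = normalize_tomogram(vscene.tomogram)
        model = build_model(ModelConfig(n_classes=2, base_channels=8, seed=1))
        cfg = TrainConfig(N=48, epochs=3, batch_size=4, augment=False, seed=1)
        from tomopick.infer import MPNMSConfig, TilingConfig, pick_particles, predict_scoremap
        from tomopick.metrics import match_picks, precision_recall_f1
        result = train(model, [(tomo, labels, scene.truth)], cfg,
                       validation=(vtomo, vscene.truth),
                       tiling=TilingConfig(N=48, pad_size=0), particle_r=4,
                       match_r=4.5)
        # the restored model reproduces its recorded validation score
        score = predict_scoremap(model, vtomo, TilingConfig(N=48, pad_size=0))
        picks = pick_particles(score, MPNMSConfig(), {1: 4})
        p, r, _ = precision_recall_f1(match_picks(picks, vscene.truth, 4.5))
        recorded = result.history[result.best_epoch - 1]
        assert f1_alpha(p, r, cfg.alpha) == pytest.approx(result.best_f1_alpha, abs=1e-9)
        assert recorded["val_F1a"] == pytest.approx(result.best_f1_alpha)
        # the selected epoch is the argmax of the history
        best_scan = max(row["val_F1a"] for row in result.history)
        assert result.best_f1_alpha == pytest.approx(best_scan)

    def test_empty_training_set_rejected(self):
        model = build_model(ModelConfig(n_classes=2, base_channels=4))
        with pytest.raises(ValueError, match="empty"):
            train(model, [], TrainConfig(N=16, epochs=1))
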