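"""MP-NMS center extraction and overlap-tile inference."""

import numpy as np
import pytest

from tomopick.io import ParticleSet, Tomogram
from tomopick.labels import MaskSpec, generate_mask, paint_labels
from tomopick.model import ScoreMap
from tomopick.infer import (
    MPNMSConfig, TilingConfig, binarize, min_iterations, mp_nms,
    pick_particles, predict_scoremap, receptive_field,
)


def oracle_mp_nms(binary, k, n_iter):
    """Direct nested-loop mean filter + 26-neighborhood maximum scan."""
    soft = binary.astype(np.int64)
    r = k // 2
    d, h, w = binary.shape
    for _ in range(n_iter):
        out = np.zeros_like(soft)
        for z in range(d):
            for y in range(h):
                for x in range(w):
                    s = 0
                    for dz in range(-r, r + 1):
                        for dy in range(-r, r + 1):
                            for dx in range(-r, r + 1):
                                zz, yy, xx = z + dz, y + dy, x + dx
                                if 0 <= zz < d and 0 <= yy < h and 0 <= xx < w:
                                    s += soft[zz, yy, xx]
                    out[z, y, x] = s
        soft = out
    maxima = []
    for z in range(d):
        for y in range(h):
            for x in range(w):
                v = soft[z, y, x]
                if v <= 0:
                    continue
                ok = True
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if not (0 <= zz < d and 0 <= yy < h and 0 <= xx < w):
                                continue
                            n = soft[zz, yy, xx]
                            if n > v or (n == v and (dz, dy, dx) < (0, 0, 0)):
                                ok = False
                if ok:
                    maxima.append((z, y, x))
    return soft / float(k) ** (3 * n_iter), maxima


class TestReceptiveField:
    @pytest.mark.parametrize("k,i,expected", [(3, 0, 1), (3, 11, 23), (5, 3, 13)])
    def test_values(self, k, i, expected):
        assert receptive_field(k, i) == expected

    @pytest.mark.parametrize("r,k,expected", [(3, 3, 3), (12, 3, 12), (5, 5, 3)])
    def test_min_iterations(self, r, k, expected):
        assert min_iterations(r, k) == expected

    def test_min_iterations_covers_diameter(self):
        for r in range(1, 13):
            for k in (3, 5, 7):
                assert receptive_field(k, min_iterations(r, k)) >= 2 * r + 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            receptive_field(4, 1)
        with pytest.raises(ValueError):
            min_iterations(0, 3)


class TestBinarize:
    def test_below_threshold_zero(self):
        assert not binarize(np.full((2, 2, 2), 0.4), 0.5).any()

    def test_zero_threshold_all_one(self):
        assert binarize(np.zeros((2, 2, 2)), 0.0).all()

    def test_mixed_grid(self):
        s = np.array([[[0.9, 0.1], [0.5, 0.49]], [[0.0, 1.0], [0.51, 0.2]]])
        np.testing.assert_array_equal(
            binarize(s, 0.5),
            [[[1, 0], [1, 0]], [[0, 1], [1, 0]]])


class TestMPNMS:
    def test_single_ball_single_maximum(self):
        ball = generate_mask(MaskSpec("ball", 3, 1))
        vol = np.zeros((41, 41, 41), dtype=np.uint8)
        vol[17:24, 17:24, 17:24] = (ball > 0)
        soft, maxima = mp_nms(vol, k=3, n_iter=3)
        assert len(maxima) == 1
        assert maxima[0][0] == (20, 20, 20)

    def test_two_balls_two_maxima(self):
        ball = generate_mask(MaskSpec("ball", 3, 1)) > 0
        vol = np.zeros((41, 41, 41), dtype=np.uint8)
        for c in [(15, 20, 20), (25, 20, 20)]:
            vol[c[0] - 3:c[0] + 4, c[1] - 3:c[1] + 4, c[2] - 3:c[2] + 4] |= ball
        _, maxima = mp_nms(vol, k=3, n_iter=3)
        assert sorted(pos for pos, _ in maxima) == [(15, 20, 20), (25, 20, 20)]

    def test_all_zero_empty(self):
        _, maxima = mp_nms(np.zeros((8, 8, 8), dtype=np.uint8), 3, 3)
        assert maxima == []

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            mp_nms(np.full((4, 4, 4), 2), 3, 1)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            vol = (rng.random((12, 12, 12)) < 0.3).astype(np.uint8)
            soft, maxima = mp_nms(vol, 3, 3)
            ref_soft, ref_maxima = oracle_mp_nms(vol, 3, 3)
            np.testing.assert_array_equal(soft, ref_soft)
            assert sorted(pos for pos, _ in maxima) == sorted(ref_maxima)

    def test_mean_filter_conservation(self):
        # one MP iteration preserves the total mass when the foreground is
        # at least k voxels away from every border
        vol = np.zeros((20, 20, 20), dtype=np.uint8)
        vol[8:12, 8:12, 8:12] = 1
        soft, _ = mp_nms(vol, 3, 1)
        assert soft.sum() == pytest.approx(vol.sum(), rel=1e-12)

    def test_plateau_yields_single_candidate(self):
        vol = np.zeros((10, 10, 10), dtype=np.uint8)
        vol[:, :, :] = 1  # global plateau after zero iterations of MP
        _, maxima = mp_nms(vol, 3, 1)
        # interior plateau: exactly the lexicographically-first qualifying
        # voxel of each local plateau survives; the corner-adjacent interior
        # voxel (1,1,1) has all-equal interior neighbors and wins there
        positions = [pos for pos, _ in maxima]
        assert len(positions) == len(set(positions))
        assert len(positions) >= 1


class TestPickParticles:
    def test_dedup_keeps_larger(self):
        from tomopick.infer import _deduplicate
        maxima = [((0, 0, 0), 0.9), ((0, 0, 2), 0.7)]
        kept = _deduplicate(maxima, t_dist=3.0)
        assert kept == [((0, 0, 0), 0.9)]
        # at or beyond t_dist both survive (strictly-closer rule)
        assert len(_deduplicate([((0, 0, 0), 0.9), ((0, 0, 3), 0.7)], 3.0)) == 2

    def test_t_lm_above_max_empty(self):
        lv = paint_labels((32, 32, 32),
                          ParticleSet.from_arrays([[16, 16, 16]], 1),
                          {1: MaskSpec("tball", 3, 1)})
        score = np.stack([1.0 - (lv.data > 0), (lv.data > 0)]).astype(np.float32)
        picks = pick_particles(ScoreMap(score), MPNMSConfig(t_lm=2.0), {1: 3})
        assert len(picks) == 0

    def test_fifteen_tballs_self_consistency(self):
        rng = np.random.default_rng(0)
        centers = []
        while len(centers) < 15:
            c = rng.integers(6, 58, size=3)
            if not centers or np.min(np.linalg.norm(np.array(centers) - c, axis=1)) >= 10:
                centers.append(c)
        truth = ParticleSet.from_arrays(np.array(centers, dtype=float), 1)
        lv = paint_labels((64, 64, 64), truth, {1: MaskSpec("tball", 3, 1)})
        score = np.stack([1.0 - (lv.data > 0), (lv.data > 0)]).astype(np.float32)
        picks = pick_particles(ScoreMap(score), MPNMSConfig(), {1: 3})
        assert len(picks) == 15
        pc = np.sort(picks.centers(), axis=0)
        tc = np.sort(truth.centers(), axis=0)
        assert np.max(np.abs(pc - tc)) <= 1.0

    def test_scores_normalized_to_unit_max(self):
        lv = paint_labels((32, 32, 32),
                          ParticleSet.from_arrays([[10, 10, 10], [10, 10, 22]], 1),
                          {1: MaskSpec("ball", 3, 1)})
        score = np.stack([1.0 - (lv.data > 0), (lv.data > 0)]).astype(np.float32)
        picks = pick_particles(ScoreMap(score), MPNMSConfig(), {1: 3})
        assert max(p.score for p in picks) == pytest.approx(1.0)

    def test_embedding_offset_idempotence(self):
        """Picks from a volume embedded in a larger zero background differ
        from the original picks exactly by the embedding offset."""
        lv = paint_labels((32, 32, 32),
                          ParticleSet.from_arrays([[12, 14, 16], [24, 10, 20]], 1),
                          {1: MaskSpec("tball", 3, 1)})
        small = (lv.data > 0).astype(np.float32)
        big = np.zeros((48, 48, 48), dtype=np.float32)
        off = (8, 4, 12)
        big[8:40, 4:36, 12:44] = small
        for vol, offset in [(small, (0, 0, 0)), (big, off)]:
            score = np.stack([1.0 - vol, vol])
            picks = pick_particles(ScoreMap(score), MPNMSConfig(), {1: 3})
            got = np.sort(picks.centers() - np.array(offset), axis=0)
            if offset == (0, 0, 0):
                base = got
        np.testing.assert_array_equal(base, got)


class _ConstantModel:
    """Mock model: fixed probabilities everywhere, any tile size."""

    def __init__(self, n_classes=2, p_fg=0.7):
        from tomopick.model import ModelConfig
        self.config = ModelConfig(n_classes=n_classes, base_channels=4)
        self.p_fg = p_fg

    def predict_proba(self, tile):
        out = np.empty((self.config.n_classes,) + tile.shape, dtype=np.float32)
        out[0] = 1.0 - self.p_fg
        out[1:] = self.p_fg / (self.config.n_classes - 1)
        return ScoreMap(out)


class TestPredictScoremap:
    def test_constant_model_seamless_stitching(self):
        tomo = Tomogram(np.random.default_rng(0).normal(size=(40, 48, 56)).astype(np.float32))
        sm = predict_scoremap(_ConstantModel(), tomo, TilingConfig(N=24, pad_size=4))
        assert sm.data.shape == (2, 40, 48, 56)
        np.testing.assert_allclose(sm.data[1], 0.7, atol=1e-6)

    def test_single_tile_equals_direct_output(self, rng):
        from tomopick.model import ModelConfig, build_model
        m = build_model(ModelConfig(n_classes=2, base_channels=4, seed=1))
        vol = rng.normal(size=(24, 24, 24)).astype(np.float32)
        direct = m.predict_proba(vol).data
        tiled = predict_scoremap(m, Tomogram(vol), TilingConfig(N=24, pad_size=0)).data
        np.testing.assert_array_equal(direct, tiled)

    def test_tiling_config_invariants(self):
        with pytest.raises(ValueError):
            TilingConfig(N=30, pad_size=2)
        with pytest.raises(ValueError):
            TilingConfig(N=32, pad_size=16)
        assert TilingConfig(N=48, pad_size=8).stride == 32

    def test_volume_smaller_than_tile_rejected(self):
        tomo = Tomogram(np.zeros((16, 16, 16), dtype=np.float32))
        with pytest.raises(ValueError, match="smaller than tile"):
            predict_scoremap(_ConstantModel(), tomo, TilingConfig(N=48, pad_size=8))


class TestCrossClassDedup:
    def test_coincident_picks_of_two_classes_suppressed(self):
        lv = paint_labels((24, 24, 24),
                          ParticleSet.from_arrays([[12, 12, 12]], 1),
                          {1: MaskSpec("ball", 3, 1)})
        fg = (lv.data > 0).astype(np.float32)
        # both foreground classes see the same blob
        score = np.stack([1.0 - fg, fg, fg]).astype(np.float32)
        both = pick_particles(ScoreMap(score), MPNMSConfig(), {1: 3, 2: 3})
        assert len(both) == 2
        deduped = pick_particles(ScoreMap(score), MPNMSConfig(), {1: 3, 2: 3},
                                 cross_class_dedup=True)
        assert len(deduped) == 1
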