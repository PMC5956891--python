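"""Voxel-resolution texture bank: counts, border handling, oracle agreement."""

import numpy as np
import pytest

from mpcad.config import VoxelFeatureConfig
from mpcad.glcm import GLCM_STAT_NAMES
from mpcad.voxel_features import (GLCM_OFFSETS, build_voxel_feature_bank,
                                  feature_bank_names, first_order_features,
                                  gabor_features, glcm_voxel_features,
                                  kirsch_features)

from .oracles import cooccurrence_pairs, glcm_stats_oracle, quantize_minmax


class TestFirstOrder:
    def test_constant_patch(self):
        img = np.full((7, 7), 5.0)
        mask = np.zeros((7, 7), bool)
        mask[3, 3] = True
        feats = first_order_features(img, mask, window=3)
        assert feats[0] == pytest.approx([5.0, 0.0, 0.0, 0.0])

    def test_printed_three_by_three_patch(self):
        """Window over the digits 1..9: mean 5, population SD of {1..9}."""
        img = np.arange(1, 10, dtype=float).reshape(3, 3)
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        feats = first_order_features(img, mask, window=3)[0]
        vals = np.arange(1, 10)
        assert feats[0] == pytest.approx(5.0)
        assert feats[1] == pytest.approx(np.sqrt(np.mean((vals - 5.0) ** 2)))
        m2 = np.mean((vals - 5.0) ** 2)
        assert feats[2] == pytest.approx(np.mean((vals - 5.0) ** 4) / m2 ** 2 - 3)
        assert feats[3] == pytest.approx(0.0, abs=1e-12)

    def test_border_window_is_clipped_and_finite(self):
        img = np.arange(25, dtype=float).reshape(5, 5)
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        feats = first_order_features(img, mask, window=3)[0]
        window_vals = img[:2, :2].ravel()
        assert feats[0] == pytest.approx(window_vals.mean())
        assert np.all(np.isfinite(feats))

    def test_matches_direct_statistics_on_random_patches(self, rng):
        from scipy import stats as sstats
        img = rng.normal(size=(9, 9))
        mask = np.ones((9, 9), bool)
        feats = first_order_features(img, mask, window=5)
        r, c = 4, 4
        w = img[2:7, 2:7].ravel()
        row = feats[np.ravel_multi_index((r, c), (9, 9))]
        assert row[0] == pytest.approx(w.mean())
        assert row[1] == pytest.approx(w.std())
        assert row[2] == pytest.approx(sstats.kurtosis(w, fisher=True, bias=True))
        assert row[3] == pytest.approx(sstats.skew(w, bias=True))


class TestGlcmVoxel:
    def test_constant_window_fallbacks(self):
        img = np.full((5, 5), 3.0)
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        out = glcm_voxel_features(img, mask, window=5, levels=8)[0]
        stats = dict(zip(GLCM_STAT_NAMES, out[:18]))
        assert stats["energy"] == pytest.approx(1.0)
        assert stats["contrast"] == pytest.approx(0.0)
        assert stats["entropy"] == pytest.approx(0.0)
        assert stats["correlation"] == pytest.approx(0.0)

    def test_checkerboard_horizontal_pairs(self):
        """2x2 checkerboard quantised to 2 levels: all horizontal
        co-occurrence mass is off-diagonal, so contrast 1 and energy 0.5."""
        img = np.array([[0.0, 1.0], [1.0, 0.0]])
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        out = glcm_voxel_features(img, mask, window=3, levels=2,
                                  offsets=((0, 1),))[0]
        stats = dict(zip(GLCM_STAT_NAMES, out))
        assert stats["contrast"] == pytest.approx(1.0)
        assert stats["energy"] == pytest.approx(0.5)

    def test_column_count_is_72(self, rng):
        img = rng.normal(size=(8, 8))
        mask = np.ones((8, 8), bool)
        out = glcm_voxel_features(img, mask, window=5, levels=8)
        assert out.shape[1] == 18 * 4

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_pair_enumeration_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        size = int(rng.integers(3, 6))
        img = rng.normal(size=(size, size))
        levels = int(rng.integers(2, 6))
        mask = np.zeros((size, size), bool)
        r, c = rng.integers(0, size, size=2)
        mask[r, c] = True
        out = glcm_voxel_features(img, mask, window=5, levels=levels)[0]
        h = 2
        r0, r1 = max(r - h, 0), min(r + h + 1, size)
        c0, c1 = max(c - h, 0), min(c + h + 1, size)
        win = img[r0:r1, c0:c1]
        q = quantize_minmax(win, levels)
        valid = np.ones(q.shape, bool)
        for d, offset in enumerate(GLCM_OFFSETS):
            pairs = cooccurrence_pairs(q, valid, offset)
            oracle = glcm_stats_oracle(pairs, levels)
            got = dict(zip(GLCM_STAT_NAMES, out[d * 18:(d + 1) * 18]))
            for name in GLCM_STAT_NAMES:
                assert got[name] == pytest.approx(oracle[name], abs=1e-10), \
                    f"{name} offset {offset}"


class TestGaborKirsch:
    def test_gabor_grid_gives_12_columns(self, rng):
        img = rng.normal(size=(10, 10))
        out = gabor_features(img, np.ones((10, 10), bool))
        assert out.shape[1] == 12

    def test_gabor_zero_image_zero_response(self):
        out = gabor_features(np.zeros((10, 10)), np.ones((10, 10), bool))
        assert np.allclose(out, 0.0)

    def test_gabor_offset_invariance(self, rng):
        """Zero-mean kernels ignore a constant intensity offset."""
        img = rng.normal(size=(12, 12))
        mask = np.ones((12, 12), bool)
        a = gabor_features(img, mask)
        b = gabor_features(img + 37.0, mask)
        assert np.allclose(a, b, atol=1e-8 * np.abs(a).max())

    def test_kirsch_constant_image_zero(self):
        out = kirsch_features(np.full((6, 6), 9.0), np.ones((6, 6), bool))
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_kirsch_count_and_step_edge(self):
        img = np.zeros((5, 5))
        img[:, 3:] = 1.0
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        out = kirsch_features(img, mask)[0]
        assert out.shape == (8,)
        # strongest absolute response along the east/west kernels
        from mpcad.voxel_features import KIRSCH_DIRECTIONS
        strongest = {KIRSCH_DIRECTIONS[i] for i in np.flatnonzero(
            np.abs(out) == np.abs(out).max())}
        assert strongest & {"E", "W"}


class TestBank:
    def test_default_bank_has_96_named_columns(self, noiseless_case):
        mask = np.zeros(noiseless_case.shape, bool)
        mask[18:22, 18:22, 3] = True
        bank = build_voxel_feature_bank(noiseless_case.channels, mask)
        assert bank.values.shape == (16, 96)
        assert len(set(bank.feature_names)) == 96
        assert np.all(np.isfinite(bank.values))

    def test_empty_mask_gives_zero_rows(self, noiseless_case):
        mask = np.zeros(noiseless_case.shape, bool)
        bank = build_voxel_feature_bank(noiseless_case.channels, mask)
        assert bank.values.shape == (0, 96)
        assert len(bank.feature_names) == 96

    def test_bank_is_deterministic(self, noiseless_case):
        mask = np.zeros(noiseless_case.shape, bool)
        mask[17:20, 20:23, 4] = True
        a = build_voxel_feature_bank(noiseless_case.channels, mask)
        b = build_voxel_feature_bank(noiseless_case.channels, mask)
        assert np.array_equal(a.values, b.values)

    def test_missing_channel_rejected(self, noiseless_case):
        cfg = VoxelFeatureConfig()
        cfg.channel_assignment = dict(cfg.channel_assignment, gabor="nope")
        from mpcad.imaging import ConfigurationError
        with pytest.raises(ConfigurationError):
            build_voxel_feature_bank(noiseless_case.channels,
                                     np.ones(noiseless_case.shape, bool), cfg)

    def test_translation_equivariance(self, rng):
        """Shifting image and mask together shifts rows, not values."""
        img = np.zeros((64, 64, 1))
        img[28:36, 28:36, 0] = rng.normal(size=(8, 8))
        channels = {"A": img}
        cfg = VoxelFeatureConfig(channel_assignment={g: "A" for g in
                                                     ("first_order", "glcm", "gabor", "kirsch")})
        mask = np.zeros((64, 64, 1), bool)
        mask[30:34, 30:34, 0] = True
        bank_a = build_voxel_feature_bank(channels, mask, cfg)
        shifted = {"A": np.roll(img, (3, 2), axis=(0, 1))}
        mask_b = np.roll(mask, (3, 2), axis=(0, 1))
        bank_b = build_voxel_feature_bank(shifted, mask_b, cfg)
        assert np.allclose(bank_a.values, bank_b.values, atol=1e-8)

    def test_names_match_config(self):
        names = feature_bank_names(VoxelFeatureConfig())
        assert len(names) == 96
        assert sum(n.startswith("fo_") for n in names) == 4
        assert sum(n.startswith("glcm_") for n in names) == 72
        assert sum(n.startswith("gabor_") for n in names) == 12
        assert sum(n.startswith("kirsch_") for n in names) == 8
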