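"""Region feature model: morphology/asymmetry/physiology features, the
242-entry assembly, mRMR and the two-stage selection, and the classifier."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk

from mpcad.config import FmConfig
from mpcad.glcm import REGION_GLCM_STAT_NAMES
from mpcad.rd_fm import (ASYMMETRY_NAMES, SingleClassTrainingError,
                         asymmetry_features, assemble_region_vector,
                         classify_regions, label_regions, morphology_f1,
                         morphology_f2, morphology_f3, mrmr_select,
                         physiology_features, region_feature_names,
                         region_table, two_stage_selection)
from mpcad.regions import CandidateRegion, trace_boundary

from .oracles import cooccurrence_pairs, glcm_stats_oracle, quantize_minmax


def make_region(mask2d, slice_index=0, patient_id="p", region_id=0):
    return CandidateRegion(mask=mask2d.astype(bool), slice_index=slice_index,
                           region_id=region_id, patient_id=patient_id,
                           boundary=trace_boundary(mask2d))


def disk_region(radius=8, shape=(32, 32)):
    mask = np.zeros(shape, bool)
    rr, cc = draw_disk((shape[0] // 2, shape[1] // 2), radius, shape=shape)
    mask[rr, cc] = True
    return make_region(mask)


def star_region(shape=(32, 32)):
    """Spiculated star with the same rough area as the disk."""
    mask = np.zeros(shape, bool)
    cy, cx = shape[0] // 2, shape[1] // 2
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    ang = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    mask[rad < 6 + 5 * np.cos(6 * ang)] = True
    return make_region(mask)


class TestMorphology:
    def test_disk_f1_near_zero(self):
        assert morphology_f1(disk_region(), se_radius=2) < 0.05

    def test_star_f1_exceeds_disk(self):
        assert morphology_f1(star_region(), 2) > morphology_f1(disk_region(), 2)

    def test_f1_nonnegative_on_random_blobs(self, rng):
        for _ in range(5):
            mask = np.zeros((20, 20), bool)
            mask[4:16, 4:16] = rng.random((12, 12)) < 0.7
            from skimage.morphology import remove_small_objects
            from skimage import measure
            labs = measure.label(mask, connectivity=2)
            if labs.max() == 0:
                continue
            biggest = labs == np.argmax(np.bincount(labs.ravel())[1:]) + 1
            assert morphology_f1(make_region(biggest), 2) >= 0.0

    def test_circle_f2_small(self):
        assert morphology_f2(disk_region(radius=10)) < 0.02

    def test_square_f2_exceeds_circle(self):
        sq = np.zeros((32, 32), bool)
        sq[8:24, 8:24] = True
        assert morphology_f2(make_region(sq)) > morphology_f2(disk_region(radius=9))

    def test_circle_f3_near_zero(self):
        assert morphology_f3(disk_region(radius=10)) < 0.1

    def test_f3_identical_cutoffs_zero(self):
        assert morphology_f3(star_region(), low_freq=8, high_freq=8) == 0.0

    def test_f3_bounded_unit_interval(self):
        for region in (disk_region(), star_region()):
            v = morphology_f3(region)
            assert 0.0 <= v <= 1.0


class TestAsymmetry:
    def test_rectangle_is_symmetric(self):
        mask = np.zeros((20, 20), bool)
        mask[4:16, 6:14] = True
        feats = asymmetry_features(make_region(mask))
        assert feats == pytest.approx([0.0, 0.0, 0.0, 0.0], abs=1e-12)

    def test_half_area_arithmetic(self):
        """Halves of 30 and 20 voxels normalised by the whole region: 0.2."""
        a_large, a_small, whole = 30.0, 20.0, 50.0
        assert (a_large - a_small) / whole == pytest.approx(0.2)
        # and the implementation reproduces it on an L-shaped region
        mask = np.zeros((16, 16), bool)
        mask[2:12, 2:5] = True     # 30 voxels
        mask[2:12, 5:7] = True     # 20 more
        feats = dict(zip(ASYMMETRY_NAMES, asymmetry_features(make_region(mask))))
        assert 0.0 <= feats["major_whole"] <= 1.0

    def test_small_half_normaliser_dominates(self, rng):
        mask = np.zeros((24, 24), bool)
        mask[4:20, 4:12] = True
        mask[4:10, 12:18] = True
        feats = dict(zip(ASYMMETRY_NAMES, asymmetry_features(make_region(mask))))
        assert feats["major_small"] >= feats["major_whole"]
        assert feats["minor_small"] >= feats["minor_whole"]

    def test_sliver_capped_with_warning(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 2:9] = True    # 1-pixel line: one half is empty
        with pytest.warns(UserWarning):
            feats = asymmetry_features(make_region(mask), cap=10.0)
        assert np.max(feats) == 10.0


class TestPhysiology:
    def test_constant_region(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        vals = physiology_features(make_region(mask), np.full((8, 8), 7.0))
        names = ["mean", "median", "sd", "min", "max", "kurtosis", "skewness"]
        first = dict(zip(names, vals[:7]))
        second = dict(zip(REGION_GLCM_STAT_NAMES, vals[7:]))
        assert first["mean"] == first["median"] == first["min"] == first["max"] == 7.0
        assert first["sd"] == 0.0
        assert second["energy"] == pytest.approx(1.0)
        assert second["entropy"] == pytest.approx(0.0)

    def test_count_is_26(self, rng):
        mask = np.zeros((8, 8), bool)
        mask[1:7, 1:7] = True
        vals = physiology_features(make_region(mask), rng.normal(size=(8, 8)))
        assert vals.shape == (26,)

    @pytest.mark.parametrize("trial", range(10))
    def test_glcm_block_matches_pair_enumeration(self, trial):
        rng = np.random.default_rng(700 + trial)
        size = int(rng.integers(3, 7))
        img = rng.normal(size=(size, size))
        mask = rng.random((size, size)) < 0.7
        if mask.sum() < 2:
            mask[0, :2] = True
        levels = 8
        region = make_region(mask)
        got = dict(zip(REGION_GLCM_STAT_NAMES,
                       physiology_features(region, img, levels)[7:]))
        q = np.zeros_like(mask, dtype=int)
        q[mask] = quantize_minmax(img[mask], levels)
        pairs = cooccurrence_pairs(q, mask, (0, 1))
        oracle = glcm_stats_oracle(pairs, levels)
        for name in REGION_GLCM_STAT_NAMES:
            assert got[name] == pytest.approx(oracle[name], abs=1e-10), name


class TestAssembly:
    def test_vector_has_242_entries(self, noiseless_case):
        mask = np.zeros(noiseless_case.shape[:2], bool)
        mask[14:20, 19:26] = True
        region = make_region(mask, slice_index=3,
                             patient_id=noiseless_case.patient_id)
        vec = assemble_region_vector(region, noiseless_case)
        assert len(vec.values) == 242
        assert len(set(vec.names)) == 242
        assert np.all(np.isfinite(vec.values))

    def test_block_sizes_match_inventory(self):
        names = region_feature_names()
        assert sum(n.startswith("morph_") for n in names) == 3
        assert sum(n.startswith("asym_") for n in names) == 4
        assert sum(n.startswith("size_") for n in names) == 1
        assert sum(n.startswith("phys_") for n in names) == 26 * 9
        # the mask-derived block is 8 entries
        assert sum(n.startswith(("morph_", "asym_", "size_")) for n in names) == 8

    def test_missing_channel_rejected(self, noiseless_case):
        import copy
        from mpcad.imaging import ConfigurationError
        case = copy.copy(noiseless_case)
        case.channels = {k: v for k, v in case.channels.items() if k != "CDI"}
        mask = np.zeros(case.shape[:2], bool)
        mask[14:20, 19:26] = True
        with pytest.raises((ConfigurationError, Exception)):
            assemble_region_vector(make_region(mask, 3), case)


class TestMrmr:
    def test_label_copy_selected_first(self, rng):
        y = rng.integers(0, 2, size=200)
        X = np.column_stack([rng.normal(size=200), y + 0.0, rng.normal(size=200)])
        assert mrmr_select(X, y, 1)[0] == 1

    def test_duplicate_feature_not_selected_twice_in_a_row(self, rng):
        y = rng.integers(0, 2, size=400)
        informative = y + rng.normal(0, 0.1, size=400)
        weak = y + rng.normal(0, 2.0, size=400)
        X = np.column_stack([informative, informative.copy(), weak])
        sel = mrmr_select(X, y, 2)
        assert sel[0] == 0
        assert sel[1] == 2   # redundancy pushes the clone behind the weak feature

    def test_k_capped_with_warning(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, size=50)
        with pytest.warns(UserWarning):
            sel = mrmr_select(X, y, 10)
        assert len(sel) == 3


def _toy_study(rng, n_per_patient=6, n_patients=4, planted="phys_T2w_mean"):
    """Synthetic region table with one perfectly separating feature."""
    names = region_feature_names()
    rows, metas, labels = [], [], []
    for p in range(n_patients):
        for i in range(n_per_patient):
            label = i % 2
            vec = rng.normal(size=242)
            vec[names.index(planted)] = 5.0 * label + rng.normal(0, 0.05)
            rows.append(vec)
            metas.append((f"p{p}", i, 0))
            labels.append(label)
    md = pd.DataFrame(metas, columns=["patient_id", "region_id", "slice"])
    df = pd.DataFrame(np.array(rows), columns=names)
    return pd.concat([md, df], axis=1), np.array(labels)


class TestSelectionAndClassifier:
    def test_planted_feature_survives_two_stage_selection(self, rng):
        table, labels = _toy_study(rng)
        cfg = FmConfig(criterion="auc")
        plan = two_stage_selection(table, labels, cfg)
        names = region_feature_names()
        assert "phys_T2w_mean" in [names[i] for i in plan.final_selected]

    def test_selection_is_deterministic(self, rng):
        table, labels = _toy_study(rng)
        cfg = FmConfig(criterion="specificity")
        p1 = two_stage_selection(table, labels, cfg)
        p2 = two_stage_selection(table, labels, cfg)
        assert p1.to_dict() == p2.to_dict()

    def test_stage2_pool_contains_stage1_survivors(self, rng):
        table, labels = _toy_study(rng)
        plan = two_stage_selection(table, labels, FmConfig(criterion="auc"))
        pooled = set(sum(plan.per_channel_selected.values(), []) + plan.mas_selected)
        assert set(plan.final_selected) <= pooled

    def test_separable_training_is_classified_perfectly(self, rng):
        table, labels = _toy_study(rng)
        plan = two_stage_selection(table, labels, FmConfig(criterion="auc"))
        pred, scores = classify_regions(table, labels, table, plan)
        assert np.array_equal(pred, labels)
        assert np.all(scores[labels == 1] > scores[labels == 0].max())

    def test_row_permutation_invariance(self, rng):
        table, labels = _toy_study(rng)
        plan = two_stage_selection(table, labels, FmConfig(criterion="auc"))
        perm = rng.permutation(len(table))
        pred_a, _ = classify_regions(table, labels, table, plan)
        pred_b, _ = classify_regions(table.iloc[perm].reset_index(drop=True),
                                     labels[perm], table, plan)
        assert np.array_equal(pred_a, pred_b)

    def test_single_class_training_rejected(self, rng):
        table, labels = _toy_study(rng)
        plan = two_stage_selection(table, labels, FmConfig(criterion="auc"))
        with pytest.raises(SingleClassTrainingError):
            classify_regions(table, np.zeros(len(table), dtype=int), table, plan)


class TestRegionLabels:
    def test_overlap_threshold_is_strict(self):
        truth = np.zeros((10, 10, 1), bool)
        truth[0:5, 0:10, 0] = True
        mask = np.zeros((10, 10), bool)
        mask[0:10, 0:10] = True      # overlap fraction exactly 0.5
        region = make_region(mask)
        assert label_regions([region], truth, overlap_frac=0.5)[0] == 1
        truth2 = truth.copy()
        truth2[4, :, 0] = False      # overlap fraction 0.4
        assert label_regions([region], truth2, overlap_frac=0.5)[0] == 0
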