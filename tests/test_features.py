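"""Fold-internal abnormal ROIs and leakage-free feature matrices."""

import numpy as np
import pytest

from bdtaskfmri.features import (
    AbnormalROISet,
    build_feature_matrix,
    define_abnormal_rois,
    extract_roi_timeseries,
)
from bdtaskfmri.glm import StatMap
from bdtaskfmri.simulate import SimConfig, VolumeSeries, make_atlas


@pytest.fixture(scope="module")
def atlas():
    cfg = SimConfig(grid_shape=(16, 16, 16), n_regions=4, n_volumes=80,
                    n_events_per_condition=6, effect_rois=("region_01",))
    return make_atlas(cfg)


def _maps(arrays, contrast="Go-NoGo"):
    return [StatMap(values=a, df=20, contrast=contrast, level="first") for a in arrays]


def _planted_cohort(atlas, rng, region_label, delta, n_per_group=4):
    """First-level-style maps with a group shift inside one atlas region."""
    region = atlas.labels == region_label
    bd, hc = [], []
    for _ in range(n_per_group):
        base = rng.normal(0, 0.5, atlas.labels.shape)
        hc.append(base)
        shifted = rng.normal(0, 0.5, atlas.labels.shape)
        shifted[region] += delta
        bd.append(shifted)
    return _maps(bd), _maps(hc)


class TestDefineAbnormalRois:
    def test_planted_region_found_with_full_overlap(self, atlas, rng):
        bd, hc = _planted_cohort(atlas, rng, region_label=2, delta=6.0)
        rois = define_abnormal_rois(bd, hc, atlas, "Go-NoGo", 0, ("a", "b"),
                                    voxel_p=0.01, cluster_p=0.05, min_extent=10)
        assert rois.roi_labels == (2,)
        assert rois.roi_names == (atlas.names[1],)
        region_size = int((atlas.labels == 2).sum())
        assert rois.overlap_counts[0] >= 0.9 * region_size
        # every abnormal voxel lies inside the region
        for v in rois.voxel_sets[0]:
            assert atlas.labels[tuple(v)] == 2

    def test_null_maps_give_empty_set(self, atlas, rng, caplog):
        bd = _maps([rng.normal(0, 1, atlas.labels.shape) for _ in range(4)])
        hc = _maps([rng.normal(0, 1, atlas.labels.shape) for _ in range(4)])
        with caplog.at_level("INFO"):
            rois = define_abnormal_rois(bd, hc, atlas, "Go-NoGo", 3, ("a",))
        assert rois.k == 0
        assert any("empty abnormal ROI set" in r.message for r in caplog.records)

    def test_min_overlap_excludes_marginal_region(self, atlas, rng):
        bd, hc = _planted_cohort(atlas, rng, region_label=2, delta=6.0)
        region_size = int((atlas.labels == 2).sum())
        generous = define_abnormal_rois(bd, hc, atlas, "Go-NoGo", 0, ("a",),
                                        voxel_p=0.01, min_overlap=10)
        strict = define_abnormal_rois(bd, hc, atlas, "Go-NoGo", 0, ("a",),
                                      voxel_p=0.01, min_overlap=region_size + 1)
        assert generous.k == 1 and strict.k == 0

    def test_depends_only_on_train_inputs(self, atlas, rng):
        bd, hc = _planted_cohort(atlas, rng, region_label=3, delta=6.0)
        a = define_abnormal_rois(bd, hc, atlas, "Go-NoGo", 0, ("s1", "s2"), voxel_p=0.01)
        b = define_abnormal_rois(bd, hc, atlas, "Go-NoGo", 0, ("s1", "s2"), voxel_p=0.01)
        assert a.roi_labels == b.roi_labels
        for va, vb in zip(a.voxel_sets, b.voxel_sets):
            np.testing.assert_array_equal(va, vb)
        assert a.source["train_hash"] == b.source["train_hash"]
        c = define_abnormal_rois(bd, hc, atlas, "Go-NoGo", 0, ("s1", "s3"), voxel_p=0.01)
        assert a.source["train_hash"] != c.source["train_hash"]


class TestExtractRoiTimeseries:
    def _rois(self, coord_lists):
        return AbnormalROISet(
            roi_labels=tuple(range(1, len(coord_lists) + 1)),
            roi_names=tuple(f"r{i}" for i in range(len(coord_lists))),
            voxel_sets=tuple(np.asarray(c) for c in coord_lists),
            overlap_counts=tuple(len(c) for c in coord_lists),
            source={},
        )

    def test_matches_brute_force_mean(self, rng):
        data = rng.normal(size=(6, 6, 6, 12))
        bold = VolumeSeries(data=data, voxel_size_mm=3.0, tr_s=2.0)
        coords = [[(0, 0, 0), (1, 2, 3), (5, 5, 5)], [(2, 2, 2)]]
        out = extract_roi_timeseries(bold, self._rois(coords))
        assert out.shape == (12, 2)
        for j, cs in enumerate(coords):
            expected = np.mean([data[c] for c in cs], axis=0)
            np.testing.assert_allclose(out[:, j], expected, atol=1e-12)

    def test_empty_roi_rejected(self, rng):
        bold = VolumeSeries(data=rng.normal(size=(4, 4, 4, 5)), voxel_size_mm=3.0, tr_s=2.0)
        rois = self._rois([np.zeros((0, 3), dtype=int)])
        with pytest.raises(ValueError, match="zero voxels"):
            extract_roi_timeseries(bold, rois)


class TestBuildFeatureMatrix:
    def _mats(self, rng, lengths, k=2):
        return {f"s{i}": rng.normal(size=(t, k)) for i, t in enumerate(lengths)}

    def test_t_use_is_min_over_train_only(self, rng):
        mats = self._mats(rng, [30, 25, 40])
        fm = build_feature_matrix(("s0", "s1"), ("s2",), mats, ("r0", "r1"))
        assert fm.t_use == 25  # s2's 40 must not matter
        assert fm.values.shape == (3, 50)

    def test_roi_major_vectorization_and_column_index(self, rng):
        mats = {"a": rng.normal(size=(5, 3)), "b": rng.normal(size=(5, 3))}
        fm = build_feature_matrix(("a",), ("b",), mats, ("r0", "r1", "r2"))
        raw = mats["b"]
        for roi in range(3):
            for t in range(5):
                col = fm.column_index(roi, t)
                assert fm.column_to_roi_timepoint(col) == (roi, t)
                expected = (raw[t, roi] - fm.scaler_center[col]) / fm.scaler_scale[col]
                assert fm.values[1, col] == pytest.approx(expected)

    def test_scaler_fitted_on_train_only(self, rng):
        mats = self._mats(rng, [20, 20, 20, 20])
        train, test = ("s0", "s1", "s2"), ("s3",)
        fm = build_feature_matrix(train, test, mats, ("r0", "r1"))
        train_rows = fm.values[:3]
        np.testing.assert_allclose(train_rows.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(train_rows.std(axis=0), 1.0, atol=1e-10)
        # perturbing the TEST subject leaves center/scale untouched
        mats2 = dict(mats)
        mats2["s3"] = mats["s3"] + 100.0
        fm2 = build_feature_matrix(train, test, mats2, ("r0", "r1"))
        np.testing.assert_allclose(fm2.scaler_center, fm.scaler_center, atol=1e-12)
        np.testing.assert_allclose(fm2.scaler_scale, fm.scaler_scale, atol=1e-12)
        np.testing.assert_allclose(fm2.values[:3], fm.values[:3], atol=1e-12)

    def test_short_test_subject_rejected(self, rng):
        mats = self._mats(rng, [20, 20, 10])
        with pytest.raises(ValueError, match="fewer than T_use"):
            build_feature_matrix(("s0", "s1"), ("s2",), mats, ("r0", "r1"))

    def test_constant_column_gets_unit_scale(self, rng):
        mats = {"a": np.ones((4, 1)), "b": np.ones((4, 1)), "c": rng.normal(size=(4, 1))}
        fm = build_feature_matrix(("a", "b"), ("c",), mats, ("r0",))
        assert np.all(fm.scaler_scale == 1.0)
        np.testing.assert_allclose(fm.values[:2], 0.0, atol=1e-12)

    def test_inconsistent_k_rejected(self, rng):
        mats = {"a": rng.normal(size=(5, 2)), "b": rng.normal(size=(5, 3))}
        with pytest.raises(ValueError, match="ROI count"):
            build_feature_matrix(("a",), ("b",), mats, ("r0", "r1"))

    def test_index_bounds(self, rng):
        mats = {"a": rng.normal(size=(5, 2)), "b": rng.normal(size=(5, 2))}
        fm = build_feature_matrix(("a",), ("b",), mats, ("r0", "r1"))
        with pytest.raises(IndexError):
            fm.column_index(2, 0)
        with pytest.raises(IndexError):
            fm.column_index(0, 5)
        with pytest.raises(IndexError):
            fm.column_to_roi_timepoint(10)
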