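"""Random-field smoothness, cluster labeling and GRF correction."""

import math

import numpy as np
import pytest
from scipy import ndimage, stats

from bdtaskfmri.rft import (
    Cluster,
    ClusterSet,
    SmoothnessEstimate,
    _cluster_p_corrected,
    _expected_clusters,
    estimate_smoothness,
    grf_cluster_correct,
    label_clusters,
)

OFFSETS_18 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if 0 < abs(dx) + abs(dy) + abs(dz) <= 2
]


def flood_fill_18(mask: np.ndarray) -> list[set]:
    """Brute-force 18-connectivity components as sets of coordinate tuples."""
    mask = mask.copy()
    comps = []
    while mask.any():
        seed = tuple(np.argwhere(mask)[0])
        stack, comp = [seed], {seed}
        mask[seed] = False
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in OFFSETS_18:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)) and mask[p]:
                    mask[p] = False
                    comp.add(p)
                    stack.append(p)
        comps.append(comp)
    return comps


def _smooth_unit_field(rng, shape, fwhm_vox):
    sigma = fwhm_vox / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="wrap")
    return f / f.std()


class TestLabelClusters:
    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((9, 9, 9)) < 0.15
            got = [set(map(tuple, c)) for c in label_clusters(mask)]
            expected = flood_fill_18(mask)
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected))

    def test_corner_neighbors_are_separate_clusters(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = mask[2, 2, 2] = True  # share only a corner
        assert len(label_clusters(mask)) == 2

    def test_edge_neighbors_merge(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = mask[2, 2, 1] = True  # share an edge
        assert len(label_clusters(mask)) == 1

    def test_deterministic_order(self, rng):
        mask = rng.random((8, 8, 8)) < 0.2
        a = label_clusters(mask)
        b = label_clusters(mask)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca, cb)

    def test_empty_volume(self):
        assert label_clusters(np.zeros((5, 5, 5), bool)) == []


class TestSmoothness:
    def test_white_noise_fwhm_near_one_voxel(self, rng):
        maps = rng.normal(size=(8, 20, 20, 20))
        est = estimate_smoothness(maps, np.ones((20, 20, 20), bool))
        for f in est.fwhm_voxels:
            # white noise roughness lambda = 2 -> FWHM = sqrt(2 ln 2) ~ 1.18
            assert f == pytest.approx(math.sqrt(2 * math.log(2)), rel=0.25)

    @pytest.mark.parametrize("fwhm", [2.0, 3.0, 4.0])
    def test_recovers_known_kernel(self, rng, fwhm):
        maps = np.stack([_smooth_unit_field(rng, (24, 24, 24), fwhm) for _ in range(6)])
        est = estimate_smoothness(maps, np.ones((24, 24, 24), bool))
        for f in est.fwhm_voxels:
            assert f == pytest.approx(fwhm, rel=0.15)

    def test_resels_definition(self, rng):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        maps = rng.normal(size=(4, 10, 10, 10))
        est = estimate_smoothness(maps, mask)
        fx, fy, fz = est.fwhm_voxels
        assert est.n_voxels_search == 216
        assert est.resels == pytest.approx(216 / (fx * fy * fz))

    def test_mask_not_mutated(self, rng):
        mask = np.ones((8, 8, 8), bool)
        before = mask.copy()
        estimate_smoothness(rng.normal(size=(3, 8, 8, 8)), mask)
        np.testing.assert_array_equal(mask, before)

    def test_single_map_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            estimate_smoothness(rng.normal(size=(1, 6, 6, 6)), np.ones((6, 6, 6), bool))

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="mask"):
            estimate_smoothness(rng.normal(size=(3, 6, 6, 6)), np.zeros((6, 6, 6), bool))


class TestClusterP:
    def test_monotone_decreasing_in_extent(self):
        ps = [_cluster_p_corrected(k, 3.1, 100.0, 10000) for k in (5, 20, 80, 320)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_monotone_increasing_in_search_volume(self):
        # at fixed resels and u, a larger search volume means larger expected
        # cluster size, so a fixed extent is less surprising
        p1 = _cluster_p_corrected(50, 3.1, 100.0, 5000)
        p2 = _cluster_p_corrected(50, 3.1, 100.0, 50000)
        assert p1 < p2

    def test_expected_clusters_positive_above_one(self):
        assert _expected_clusters(3.1, 100.0) > 0
        assert _expected_clusters(1.0, 100.0) == 0.0

    def test_p_in_unit_interval(self):
        for k in (1, 10, 1000):
            for u in (2.5, 3.1, 4.0):
                p = _cluster_p_corrected(k, u, 200.0, 13824)
                assert 0.0 <= p <= 1.0


class TestGrfClusterCorrect:
    def _smoothness(self):
        return SmoothnessEstimate(fwhm_voxels=(3.0, 3.0, 3.0), resels=512.0, n_voxels_search=13824)

    def test_huge_blob_survives_noise_does_not(self, rng):
        z = rng.normal(0, 0.5, size=(24, 24, 24))
        z[6:14, 6:14, 6:14] = 8.0
        cs, mask = grf_cluster_correct(z, self._smoothness())
        assert len(cs.clusters) == 1
        cl = cs.clusters[0]
        assert cl.sign == 1 and cl.size == 512 and cl.peak_z == 8.0
        expected = np.zeros_like(mask)
        expected[6:14, 6:14, 6:14] = True
        np.testing.assert_array_equal(mask, expected)

    def test_two_sided_sign_symmetry(self, rng):
        z = rng.normal(0, 0.5, size=(20, 20, 20))
        z[3:9, 3:9, 3:9] = 7.0
        z[12:18, 12:18, 12:18] = -7.0
        cs, _ = grf_cluster_correct(z, self._smoothness())
        assert sorted(c.sign for c in cs.clusters) == [-1, 1]
        neg_cs, _ = grf_cluster_correct(-z, self._smoothness())
        assert sorted(c.sign for c in neg_cs.clusters) == [-1, 1]
        sizes = sorted(c.size for c in cs.clusters)
        assert sizes == sorted(c.size for c in neg_cs.clusters)

    def test_min_extent_removes_small_clusters(self):
        # a 64-voxel block is comfortably significant (p ~ 1e-4 here), so the
        # min_extent rule is the only thing separating the two calls
        z = np.zeros((16, 16, 16))
        z[2:6, 2:6, 2:6] = 9.0
        cs, mask = grf_cluster_correct(z, self._smoothness(), min_extent=100)
        assert cs.clusters == ()
        assert not mask.any()
        cs2, _ = grf_cluster_correct(z, self._smoothness(), min_extent=64)
        assert len(cs2.clusters) == 1
        assert cs2.clusters[0].p_corrected < 0.025

    def test_forming_threshold_value(self):
        cs, _ = grf_cluster_correct(np.zeros((8, 8, 8)), self._smoothness(), voxel_p=0.001)
        assert cs.forming_threshold_z == pytest.approx(stats.norm.ppf(1 - 0.0005))
        cs1, _ = grf_cluster_correct(
            np.zeros((8, 8, 8)), self._smoothness(), voxel_p=0.001, two_sided=False
        )
        assert cs1.forming_threshold_z == pytest.approx(stats.norm.ppf(1 - 0.001))

    def test_search_mask_restricts_clusters(self, rng):
        z = np.zeros((16, 16, 16))
        z[2:8, 2:8, 2:8] = 8.0
        search = np.zeros((16, 16, 16), bool)
        search[10:, 10:, 10:] = True
        cs, mask = grf_cluster_correct(z, self._smoothness(), mask=search)
        assert cs.clusters == () and not mask.any()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_invalid_alpha_rejected(self, bad):
        with pytest.raises(ValueError, match="voxel_p|cluster_p"):
            grf_cluster_correct(np.zeros((6, 6, 6)), self._smoothness(), voxel_p=bad)

    def test_cluster_mask_roundtrip(self, rng):
        coords = np.argwhere(rng.random((10, 10, 10)) < 0.1)
        cl = Cluster(label=1, voxels=coords, size=len(coords), peak_z=5.0, sign=1, p_corrected=0.01)
        cs = ClusterSet(clusters=(cl,), forming_threshold_z=3.0, min_extent=1)
        mask = cs.mask((10, 10, 10))
        np.testing.assert_array_equal(np.argwhere(mask), coords[np.lexsort(coords.T[::-1])])
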