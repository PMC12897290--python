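"""Gaussian-random-field cluster-level correction of z-maps.

Thresholds a z-map at a voxelwise forming threshold (two-sided, alpha split
evenly across tails), labels suprathreshold clusters under 18-connectivity
(faces + edges, the SPM convention), and assigns each cluster a family-wise
corrected p-value from the classic 3D Gaussian-field cluster-extent
approximation:

  * expected number of clusters above u:  E[m] = R * (4 ln 2)^{3/2}
    (2 pi)^{-2} (u^2 - 1) exp(-u^2 / 2), with R the RESEL count of the
    search volume;
  * expected suprathreshold volume:       E[N] = S * Phi(-u) voxels;
  * cluster extent tail (3D):             P(n >= k) = exp(-beta k^{2/3}),
    beta = [Gamma(5/2) E[m] / E[N_resel-scaled]]^{2/3} in voxel units via
    E[n] = E[N] / E[m];
  * corrected p for one cluster:          1 - exp(-E[m] P(n >= k)).

Smoothness (per-axis FWHM in voxels, hence RESELs) is estimated from the
variance of spatial first differences of standardized residual maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, special, stats

FOUR_LN_2 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class SmoothnessEstimate:
    fwhm_voxels: tuple[float, float, float]
    resels: float
    n_voxels_search: int


@dataclass(frozen=True)
class Cluster:
    label: int
    voxels: np.ndarray  # (k, 3) integer coordinates
    size: int
    peak_z: float
    sign: int  # +1 or -1
    p_corrected: float


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[Cluster, ...]
    forming_threshold_z: float
    min_extent: int

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Binary union of all retained clusters."""
        out = np.zeros(shape, dtype=bool)
        for cl in self.clusters:
            out[tuple(cl.voxels.T)] = True
        return out


def estimate_smoothness(residual_maps: np.ndarray | list, mask: np.ndarray) -> SmoothnessEstimate:
    """Per-axis FWHM (voxels) and RESELs from residual spatial roughness.

    Each residual map is standardized within the mask; the variance of first
    differences along each axis, pooled over maps, estimates the roughness
    lambda of the unit-variance field, and FWHM = sqrt(4 ln 2 / lambda).
    RESELs = masked voxel count / product of per-axis FWHMs.
    """
    maps = np.asarray(residual_maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[None]
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 residual maps")
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty search mask")
    fwhm = []
    for axis in range(3):
        num = 0.0
        den = 0
        for m in maps:
            vals = m[mask]
            sd = vals.std()
            if sd == 0:
                raise ValueError("zero-variance residual map")
            sm = (m - vals.mean()) / sd
            d = np.diff(sm, axis=axis)
            both = mask[
                tuple(slice(0, -1) if a == axis else slice(None) for a in range(3))
            ] & mask[tuple(slice(1, None) if a == axis else slice(None) for a in range(3))]
            num += float(np.sum(d[both] ** 2))
            den += int(both.sum())
        lam = num / max(den, 1)
        if lam <= 0:
            raise ValueError("zero-variance residuals along an axis")
        fwhm.append(math.sqrt(FOUR_LN_2 / lam))
    resels = n_vox / (fwhm[0] * fwhm[1] * fwhm[2])
    return SmoothnessEstimate(
        fwhm_voxels=(fwhm[0], fwhm[1], fwhm[2]), resels=resels, n_voxels_search=n_vox
    )


#: 18-connectivity structuring element: faces + edges, not corners.
STRUCTURE_18 = ndimage.generate_binary_structure(3, 2)


def label_clusters(binary: np.ndarray, structure: np.ndarray = STRUCTURE_18) -> list[np.ndarray]:
    """Connected components of a binary volume, 18-connectivity by default.

    Returns one (k, 3) coordinate array per component, ordered by each
    component's minimum linear voxel index (deterministic).
    """
    binary = np.asarray(binary, dtype=bool)
    labeled, n = ndimage.label(binary, structure=structure)
    comps = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labeled == lab)
        comps.append(coords)
    comps.sort(key=lambda c: int(np.ravel_multi_index(tuple(c[0]), binary.shape)))
    return comps


def _expected_clusters(u: float, resels: float) -> float:
    """Expected number of suprathreshold clusters (3D EC density * RESELs)."""
    return resels * FOUR_LN_2**1.5 * (2.0 * math.pi) ** -2 * (u**2 - 1.0) * math.exp(-(u**2) / 2.0)


def _cluster_p_corrected(k: int, u: float, resels: float, n_voxels: int) -> float:
    """Family-wise corrected p for a cluster of k voxels at threshold u."""
    em = _expected_clusters(u, resels)
    if em <= 0:
        return 1.0
    en_vox = n_voxels * stats.norm.sf(u) / em  # expected cluster size in voxels
    if en_vox <= 0:
        return 1.0
    beta = (special.gamma(2.5) / en_vox) ** (2.0 / 3.0)
    p_tail = math.exp(-beta * k ** (2.0 / 3.0))
    return -math.expm1(-em * p_tail)


def grf_cluster_correct(
    zmap,
    smoothness: SmoothnessEstimate,
    mask: np.ndarray | None = None,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    min_extent: int = 10,
    two_sided: bool = True,
) -> tuple[ClusterSet, np.ndarray]:
    """Two-sided GRF cluster correction of a z-map.

    Forming threshold u = Phi^{-1}(1 - voxel_p / 2) applied separately to the
    +z and -z excursion sets; each tail's clusters are retained when the
    corrected p is below cluster_p / 2 (alpha split across tails) and extent
    is at least ``min_extent`` voxels. Returns the cluster set and the binary
    abnormal mask (union of retained clusters).
    """
    for name, p in (("voxel_p", voxel_p), ("cluster_p", cluster_p)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must lie in (0, 1), got {p}")
    values = zmap.values if hasattr(zmap, "values") else np.asarray(zmap, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    if two_sided:
        u = float(stats.norm.ppf(1.0 - voxel_p / 2.0))
        tail_alpha = cluster_p / 2.0
        signs = (1, -1)
    else:
        u = float(stats.norm.ppf(1.0 - voxel_p))
        tail_alpha = cluster_p
        signs = (1,)

    clusters: list[Cluster] = []
    label = 0
    for sign in signs:
        excursion = (sign * values > u) & mask
        for coords in label_clusters(excursion):
            k = coords.shape[0]
            p_corr = _cluster_p_corrected(k, u, smoothness.resels, smoothness.n_voxels_search)
            if k >= min_extent and p_corr < tail_alpha:
                label += 1
                zvals = values[tuple(coords.T)]
                peak = zvals[np.argmax(sign * zvals)]
                clusters.append(
                    Cluster(
                        label=label,
                        voxels=coords,
                        size=k,
                        peak_z=float(peak),
                        sign=sign,
                        p_corrected=float(p_corr),
                    )
                )
    cluster_set = ClusterSet(
        clusters=tuple(clusters), forming_threshold_z=u, min_extent=min_extent
    )
    return cluster_set, cluster_set.mask(values.shape)
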