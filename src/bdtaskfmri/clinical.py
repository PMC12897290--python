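"""Brain-behavior association with GRF cluster correction and BH-FDR.

For a (contrast, mood-state, group) block: per voxel, subject activation
(first-level contrast z) is regressed on a clinical/behavioral metric
(intercept + slope, no further covariates); the slope t-map is converted to
z and GRF cluster-corrected (two-sided, voxel p < 0.001, cluster p < 0.05).
For each surviving cluster, mean regional activation is extracted per
subject and a simple linear model against each metric yields a standardized
coefficient (both variables z-scored, so beta equals the Pearson
correlation) and a two-sided p. Benjamini-Hochberg FDR is applied across the
region-metric tests within each block (q < 0.05 = discovery). Patient and
control blocks are always fit separately; no pooled model exists here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import glm, rft
from .simulate import Atlas


@dataclass(frozen=True)
class AssociationResult:
    """Per-block cluster x metric association rows with q-values."""

    block: tuple[str, str, str]  # (contrast, mood_state, group)
    table: pd.DataFrame  # cluster, size, label, metric, beta, p, q, discovery


def voxelwise_metric_regression(
    subject_maps: list[glm.StatMap], metric_values: np.ndarray
) -> glm.StatMap:
    """Per-voxel simple regression of activation on a metric; slope t -> z."""
    if len(subject_maps) < 3:
        raise ValueError("need at least 3 subjects for voxelwise regression")
    x = np.asarray(metric_values, dtype=float)
    if x.std() == 0:
        raise ValueError("metric has zero variance")
    Y = np.stack([m.values for m in subject_maps], axis=-1)  # (x, y, z, n)
    n = x.size
    if Y.shape[-1] != n:
        raise ValueError("one metric value per subject map required")
    df = n - 2
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = (Y * xc).sum(axis=-1) / sxx
    resid = Y - Y.mean(axis=-1, keepdims=True) - slope[..., None] * xc
    sigma2 = (resid**2).sum(axis=-1) / df
    se2 = sigma2 / sxx
    t = np.zeros_like(slope)
    ok = se2 > 0
    t[ok] = slope[ok] / np.sqrt(se2[ok])
    z = np.zeros_like(t)
    z[ok] = glm.t_to_z(t[ok], df)
    return glm.StatMap(values=z, df=float(df), contrast=subject_maps[0].contrast, level="second")


def metric_regression_clusters(
    subject_maps: list[glm.StatMap],
    metric_values: np.ndarray,
    atlas: Atlas,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    min_extent: int = 10,
) -> rft.ClusterSet:
    """GRF-corrected clusters of the voxelwise metric-regression z-map."""
    zmap = voxelwise_metric_regression(subject_maps, metric_values)
    residuals = glm.second_level_residuals(subject_maps)
    smoothness = rft.estimate_smoothness(residuals, atlas.brain_mask)
    clusters, _ = rft.grf_cluster_correct(
        zmap,
        smoothness,
        mask=atlas.brain_mask,
        voxel_p=voxel_p,
        cluster_p=cluster_p,
        min_extent=min_extent,
    )
    return clusters


def anatomical_label(cluster: rft.Cluster, atlas: Atlas) -> str:
    """Majority-overlap atlas region name(s) for a cluster."""
    labs = atlas.labels[tuple(cluster.voxels.T)]
    labs = labs[labs > 0]
    if labs.size == 0:
        return "background"
    vals, counts = np.unique(labs, return_counts=True)
    best = vals[counts == counts.max()]
    return "+".join(atlas.names[v - 1] for v in sorted(best))


def cluster_mean_and_fit(
    clusters: rft.ClusterSet,
    subject_maps: list[glm.StatMap],
    metrics: dict[str, np.ndarray],
    atlas: Atlas,
) -> pd.DataFrame:
    """Per (cluster, metric): standardized beta (= Pearson r) and two-sided p."""
    if not clusters.clusters:
        raise ValueError("no surviving clusters to fit")
    stacked = np.stack([m.values for m in subject_maps], axis=0)
    rows = []
    for cl in clusters.clusters:
        mean_act = stacked[(slice(None), *cl.voxels.T)].mean(axis=1)
        label = anatomical_label(cl, atlas)
        for metric_name, values in metrics.items():
            x = np.asarray(values, dtype=float)
            r, p = stats.pearsonr(mean_act, x)
            rows.append(
                {
                    "cluster": cl.label,
                    "size": cl.size,
                    "label": label,
                    "metric": metric_name,
                    "beta": float(r),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def bh_fdr(p_values: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and discovery flags.

    q-values are the monotonicity-enforced adjusted p-values; a row is a
    discovery iff q < q_level.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, q < q_level


def associate(
    subject_maps: list[glm.StatMap],
    metrics: dict[str, np.ndarray],
    atlas: Atlas,
    block: tuple[str, str, str],
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    min_extent: int = 10,
    q_level: float = 0.05,
) -> AssociationResult:
    """Full block analysis: cluster discovery per metric, fits, BH-FDR.

    Clusters are discovered from the voxelwise regression of activation on
    each metric in turn; the union of surviving clusters then feeds the
    cluster-mean linear fits, and FDR runs over all region-metric rows of
    the block jointly.
    """
    tables = []
    for metric_name, values in metrics.items():
        clusters = metric_regression_clusters(
            subject_maps,
            np.asarray(values, dtype=float),
            atlas,
            voxel_p=voxel_p,
            cluster_p=cluster_p,
            min_extent=min_extent,
        )
        if clusters.clusters:
            t = cluster_mean_and_fit(clusters, subject_maps, {metric_name: values}, atlas)
            tables.append(t)
    if not tables:
        empty = pd.DataFrame(
            columns=["cluster", "size", "label", "metric", "beta", "p", "q", "discovery"]
        )
        return AssociationResult(block=block, table=empty)
    table = pd.concat(tables, ignore_index=True)
    q, disc = bh_fdr(table["p"].to_numpy(), q_level=q_level)
    table["q"] = q
    table["discovery"] = disc
    return AssociationResult(block=block, table=table)
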