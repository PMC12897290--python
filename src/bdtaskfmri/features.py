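"""Fold-internal abnormal-ROI definition and leakage-free feature construction.

Within each outer cross-validation fold, a TRAIN-only second-level group
z-map is GRF-corrected into an abnormal voxel mask, intersected with the
atlas, and regions overlapping by at least 10 voxels become the fold's
abnormal ROIs (K of them). ROI-mean time series of each subject's
preprocessed BOLD are truncated to T_use = min over TRAIN subjects' time
points, vectorized ROI-major into 1 x (T_use * K) feature vectors, and
z-standardized per column with scaler parameters fitted on TRAIN only.
Nothing here may see TEST data: the abnormal ROI set, T_use, and the scaler
are all functions of TRAIN subjects alone.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from . import glm, rft
from .simulate import Atlas, VolumeSeries

logger = logging.getLogger(__name__)

MIN_OVERLAP_VOXELS = 10


@dataclass(frozen=True)
class AbnormalROISet:
    """Atlas regions overlapping the TRAIN-only abnormal mask by >= 10 voxels."""

    roi_labels: tuple[int, ...]  # ascending atlas labels
    roi_names: tuple[str, ...]
    voxel_sets: tuple[np.ndarray, ...]  # (k_i, 3) coords of mask ∩ region
    overlap_counts: tuple[int, ...]
    source: dict

    @property
    def k(self) -> int:
        return len(self.roi_labels)


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x (T_use * K) vectorized ROI time series, TRAIN-fitted scaling."""

    subject_ids: tuple[str, ...]
    values: np.ndarray
    t_use: int
    roi_names: tuple[str, ...]
    scaler_center: np.ndarray
    scaler_scale: np.ndarray

    def column_index(self, roi: int, timepoint: int) -> int:
        """Column id of (roi index, timepoint) under ROI-major vectorization."""
        if not (0 <= roi < len(self.roi_names)) or not (0 <= timepoint < self.t_use):
            raise IndexError("roi or timepoint out of range")
        return roi * self.t_use + timepoint

    def column_to_roi_timepoint(self, column: int) -> tuple[int, int]:
        if not (0 <= column < self.values.shape[1]):
            raise IndexError("column out of range")
        return divmod(column, self.t_use)


def _train_hash(train_ids) -> str:
    return hashlib.sha256(",".join(sorted(train_ids)).encode()).hexdigest()[:16]


def define_abnormal_rois(
    train_maps_bd: list[glm.StatMap],
    train_maps_hc: list[glm.StatMap],
    atlas: Atlas,
    contrast: str,
    fold_id: int,
    train_ids: tuple[str, ...],
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    min_extent: int = 10,
    min_overlap: int = MIN_OVERLAP_VOXELS,
) -> AbnormalROISet:
    """TRAIN-only second-level z-map -> GRF mask -> atlas intersection.

    Returns the fold's abnormal ROI set; an empty mask yields K = 0 and the
    caller must skip the fold (logged, never silent).
    """
    zmap = glm.second_level_zmap(train_maps_bd, train_maps_hc)
    residuals = np.concatenate(
        [glm.second_level_residuals(train_maps_bd), glm.second_level_residuals(train_maps_hc)]
    )
    smoothness = rft.estimate_smoothness(residuals, atlas.brain_mask)
    _, mask = rft.grf_cluster_correct(
        zmap,
        smoothness,
        mask=atlas.brain_mask,
        voxel_p=voxel_p,
        cluster_p=cluster_p,
        min_extent=min_extent,
    )
    labels, names, voxel_sets, overlaps = [], [], [], []
    for lab, name in enumerate(atlas.names, start=1):
        inter = mask & (atlas.labels == lab)
        count = int(inter.sum())
        if count >= min_overlap:
            labels.append(lab)
            names.append(name)
            voxel_sets.append(np.argwhere(inter))
            overlaps.append(count)
    if not labels:
        logger.info("fold %d (%s): empty abnormal ROI set", fold_id, contrast)
    return AbnormalROISet(
        roi_labels=tuple(labels),
        roi_names=tuple(names),
        voxel_sets=tuple(voxel_sets),
        overlap_counts=tuple(overlaps),
        source={"contrast": contrast, "fold": fold_id, "train_hash": _train_hash(train_ids)},
    )


def extract_roi_timeseries(bold: VolumeSeries, rois: AbnormalROISet) -> np.ndarray:
    """(T_i, K) matrix of ROI-mean series over each ROI's intersected voxel set."""
    cols = []
    for name, coords in zip(rois.roi_names, rois.voxel_sets):
        if coords.shape[0] == 0:
            raise ValueError(f"ROI {name} has zero voxels on this grid")
        cols.append(bold.data[tuple(coords.T)].mean(axis=0))
    return np.column_stack(cols)


def build_feature_matrix(
    train_ids: tuple[str, ...],
    test_ids: tuple[str, ...],
    matrices: dict[str, np.ndarray],
    roi_names: tuple[str, ...],
) -> FeatureMatrix:
    """Truncate to TRAIN-defined T_use, vectorize ROI-major, scale on TRAIN.

    ``matrices`` maps subject id -> (T_i, K) ROI time-series matrix. All
    subjects (TRAIN and TEST) are truncated to the first T_use rows where
    T_use = min over TRAIN subjects' T_i; a TEST subject with fewer rows than
    T_use is an error (cannot truncate to more than available).
    """
    if not train_ids:
        raise ValueError("need at least one TRAIN subject")
    ks = {matrices[s].shape[1] for s in (*train_ids, *test_ids)}
    if len(ks) != 1:
        raise ValueError(f"inconsistent ROI count across subjects: {sorted(ks)}")
    k = ks.pop()
    if k != len(roi_names):
        raise ValueError("matrix columns do not match ROI names")
    t_use = min(matrices[s].shape[0] for s in train_ids)
    if t_use < 1:
        raise ValueError("TRAIN subject with no time points")
    rows = []
    ids = (*train_ids, *test_ids)
    for sid in ids:
        m = matrices[sid]
        if m.shape[0] < t_use:
            raise ValueError(
                f"subject {sid} has {m.shape[0]} time points, fewer than T_use={t_use}"
            )
        rows.append(m[:t_use].T.reshape(-1))  # ROI-major: roi1 t1..t_use, roi2 ...
    values = np.vstack(rows)
    n_train = len(train_ids)
    center = values[:n_train].mean(axis=0)
    scale = values[:n_train].std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    values = (values - center) / scale
    return FeatureMatrix(
        subject_ids=ids,
        values=values,
        t_use=t_use,
        roi_names=roi_names,
        scaler_center=center,
        scaler_scale=scale,
    )
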