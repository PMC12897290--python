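"""First- and second-level GLM contrast z-maps.

First level: per subject, each condition's HRF-convolved boxcar plus an
intercept is fit voxelwise by ordinary least squares; a contrast weight
vector c over conditions gives t = c'b / sqrt(s2 * c'(X'X)^-1 c), converted
to a z-statistic by the probability-integral transform (log-space tails, so
high-|t| voxels never overflow to inf).

Second level: a voxelwise two-sample comparison (group-indicator GLM with
pooled variance) between patient and control first-level z-maps, again
reported as z with the fixed sign convention group A - group B (patients
minus controls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .simulate import VolumeSeries, condition_regressors

logger = logging.getLogger(__name__)

CONDITIONS = ("Go", "NoGo", "Neutral")

#: The six canonical task contrasts (weights over Go, NoGo, Neutral).
CONTRASTS: dict[str, tuple[float, float, float]] = {
    "Go-NoGo": (1.0, -1.0, 0.0),
    "Go+NoGo": (1.0, 1.0, 0.0),
    "Go-Neutral": (1.0, 0.0, -1.0),
    "NoGo-Neutral": (0.0, 1.0, -1.0),
    "Go": (1.0, 0.0, 0.0),
    "NoGo": (0.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    weights: tuple[float, ...]

    @classmethod
    def canonical(cls, name: str) -> "ContrastSpec":
        if name not in CONTRASTS:
            raise ValueError(f"unknown contrast {name!r}; expected one of {list(CONTRASTS)}")
        return cls(name=name, weights=CONTRASTS[name])


@dataclass(frozen=True)
class StatMap:
    """3D z-statistic volume with the df used in the t->z conversion."""

    values: np.ndarray
    df: float
    contrast: str
    level: str  # "first" | "second"


def t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Convert t-statistics to z via the probability-integral transform.

    Uses the upper-tail log-survival function of the t distribution and the
    log-space inverse normal CDF, so very large |t| maps to large finite z
    instead of overflowing.
    """
    t = np.asarray(t, dtype=float)
    sign = np.sign(t)
    logp = stats.t.logsf(np.abs(t), df)
    z = -special.ndtri_exp(logp)
    return sign * z


def first_level_design(
    events: pd.DataFrame, tr_s: float, n_volumes: int, conditions: tuple[str, ...] = CONDITIONS
) -> np.ndarray:
    """(n_volumes, n_conditions + 1) design: HRF-convolved boxcars + intercept."""
    for cond in conditions:
        if (events["condition"] == cond).sum() == 0:
            raise ValueError(f"condition {cond!r} has no events")
    regs = condition_regressors(events, tuple(conditions), tr_s, n_volumes)
    return np.column_stack([regs, np.ones(n_volumes)])


def _ols_contrast_z(Y: np.ndarray, X: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float]:
    """Voxelwise OLS contrast t->z. Y is (T, voxels); returns (z per voxel, df)."""
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("not enough volumes for the design")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = np.sum(resid**2, axis=0) / df
    denom2 = sigma2 * float(c @ xtx_inv @ c)
    cb = c @ beta
    z = np.zeros_like(cb)
    ok = denom2 > 0
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        logger.info("zero residual variance at %d voxels; z set to 0", n_degenerate)
    t = np.zeros_like(cb)
    t[ok] = cb[ok] / np.sqrt(denom2[ok])
    z[ok] = t_to_z(t[ok], df)
    return z, float(df)


def first_level_zmap(bold: VolumeSeries, design: np.ndarray, contrast: ContrastSpec) -> StatMap:
    """Subject-specific contrast z-map from the preprocessed series."""
    if design.shape[0] != bold.n_volumes:
        raise ValueError("design rows must match number of volumes")
    c = np.zeros(design.shape[1])
    c[: len(contrast.weights)] = contrast.weights
    Y = bold.data.reshape(-1, bold.n_volumes).T
    z, df = _ols_contrast_z(Y, design, c)
    return StatMap(
        values=z.reshape(bold.grid_shape), df=df, contrast=contrast.name, level="first"
    )


def second_level_zmap(
    maps_group_a: list[StatMap], maps_group_b: list[StatMap]
) -> StatMap:
    """Voxelwise two-sample group z-map, sign convention group A - group B.

    Group-indicator GLM with pooled (equal) variance; equivalent to the
    textbook two-sample t with df = nA + nB - 2, then converted to z.
    """
    if len(maps_group_a) < 2 or len(maps_group_b) < 2:
        raise ValueError("need at least 2 subjects per group at second level")
    shapes = {m.values.shape for m in maps_group_a + maps_group_b}
    if len(shapes) != 1:
        raise ValueError("all subject maps must share one grid")
    A = np.stack([m.values for m in maps_group_a], axis=-1)
    B = np.stack([m.values for m in maps_group_b], axis=-1)
    na, nb = A.shape[-1], B.shape[-1]
    df = na + nb - 2
    mean_diff = A.mean(axis=-1) - B.mean(axis=-1)
    ss = A.var(axis=-1, ddof=1) * (na - 1) + B.var(axis=-1, ddof=1) * (nb - 1)
    pooled = ss / df
    se2 = pooled * (1.0 / na + 1.0 / nb)
    t = np.zeros_like(mean_diff)
    ok = se2 > 0
    t[ok] = mean_diff[ok] / np.sqrt(se2[ok])
    z = np.zeros_like(t)
    z[ok] = t_to_z(t[ok], df)
    contrast = maps_group_a[0].contrast
    return StatMap(values=z, df=float(df), contrast=contrast, level="second")


def second_level_residuals(maps: list[StatMap]) -> np.ndarray:
    """Group-demeaned subject maps, stacked (n_subjects, x, y, z).

    These are the residuals of the group-indicator second-level model and the
    input to random-field smoothness estimation.
    """
    stacked = np.stack([m.values for m in maps], axis=0)
    return stacked - stacked.mean(axis=0, keepdims=True)
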