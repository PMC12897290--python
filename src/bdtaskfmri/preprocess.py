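"""Motion QC and nuisance preprocessing of realigned BOLD series.

Implements the post-realignment stages: Jenkinson framewise displacement
(FD), gross-motion exclusion (max translation > 3 mm or rotation > 3 deg),
volume-wise scrubbing (FD > 0.2 mm) absorbed via one-hot spike regressors,
Friston-24 motion + WM/CSF + linear-trend nuisance regression, 0.01-0.10 Hz
band-pass filtering, and Gaussian spatial smoothing (FWHM 4 mm). The stages
run in that order; subjects share one grid so no normalization step exists.

Motion traces store translations in mm and rotations in radians; the 3-degree
QC rule converts internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .simulate import VolumeSeries, FWHM_TO_SIGMA
from .util import check_finite

logger = logging.getLogger(__name__)

#: Radius (mm) of the sphere over which Jenkinson FD averages displacement —
#: the method's canonical constant.
FD_SPHERE_RADIUS_MM = 80.0

MAX_TRANSLATION_MM = 3.0
MAX_ROTATION_DEG = 3.0
FD_SCRUB_THRESHOLD_MM = 0.2


@dataclass(frozen=True)
class NuisanceDesign:
    """Named nuisance regressors: Friston-24, WM, CSF, trend, spike columns."""

    names: tuple[str, ...]
    values: np.ndarray  # (volumes, columns)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PreprocReport:
    fd_series: np.ndarray
    scrubbed_volumes: tuple[int, ...]
    excluded: bool
    reason: str
    params_used: dict = field(default_factory=dict)


def _rigid_affine(params: np.ndarray) -> np.ndarray:
    """4x4 rigid-body affine from (tx, ty, tz, rx, ry, rz); rotations rad."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    aff = np.eye(4)
    aff[:3, :3] = Rx @ Ry @ Rz
    aff[:3, 3] = (tx, ty, tz)
    return aff


def framewise_displacement(
    motion: np.ndarray, radius_mm: float = FD_SPHERE_RADIUS_MM
) -> np.ndarray:
    """Jenkinson RMS framewise displacement, one value per volume (mm).

    The volume-to-volume rigid transform is built from the parameter
    increments dp = p_t - p_{t-1}; writing its affine minus the identity as
    M = [A  b; 0  0], the RMS displacement of points uniformly filling a
    sphere of radius R centered at the origin of the head coordinate frame is

        FD_t = sqrt( R^2 / 5 * trace(A^T A) + b^T b ).

    FD of the first volume is defined as 0. Building the relative transform
    from increments makes FD an exact function of successive parameter
    differences (a constant offset on all volumes changes nothing); for the
    small rotations of usable scans this agrees with composing the absolute
    transforms to second order.
    """
    motion = np.asarray(motion, dtype=float)
    check_finite(motion, "motion parameters")
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (volumes, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    fd = np.zeros(motion.shape[0])
    for t in range(1, motion.shape[0]):
        M = _rigid_affine(motion[t] - motion[t - 1]) - np.eye(4)
        A = M[:3, :3]
        b = M[:3, 3]
        fd[t] = math.sqrt(radius_mm**2 / 5.0 * float(np.trace(A.T @ A)) + float(b @ b))
    return fd


def qc_exclude(motion: np.ndarray) -> tuple[bool, str]:
    """Gross-motion exclusion: any |translation| > 3 mm or |rotation| > 3 deg.

    Strict inequalities — a trace touching exactly 3 mm / 3 deg passes.
    The reason names the offending parameter and volume.
    """
    motion = np.asarray(motion, dtype=float)
    trans = np.abs(motion[:, :3])
    rot = np.abs(motion[:, 3:])
    if np.any(trans > MAX_TRANSLATION_MM):
        t, ax = np.unravel_index(np.argmax(trans), trans.shape)
        return True, (
            f"translation axis {('x', 'y', 'z')[ax]} = {trans[t, ax]:.3f} mm "
            f"> {MAX_TRANSLATION_MM} mm at volume {t}"
        )
    # compare in radians so the 3-degree boundary is exact
    if np.any(rot > math.radians(MAX_ROTATION_DEG)):
        t, ax = np.unravel_index(np.argmax(rot), rot.shape)
        return True, (
            f"rotation axis {('x', 'y', 'z')[ax]} = {math.degrees(rot[t, ax]):.3f} deg "
            f"> {MAX_ROTATION_DEG} deg at volume {t}"
        )
    return False, ""


def scrub_mask(fd_series: np.ndarray, threshold_mm: float = FD_SCRUB_THRESHOLD_MM) -> set[int]:
    """Indices of volumes with FD strictly above the scrubbing threshold."""
    fd_series = np.asarray(fd_series, dtype=float)
    return set(int(i) for i in np.flatnonzero(fd_series > threshold_mm))


def build_nuisance(
    motion: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    scrubbed: set[int] | None = None,
) -> NuisanceDesign:
    """Friston-24 + WM + CSF + linear trend + one-hot spike regressors.

    Friston-24 per motion parameter p: [p(t), p(t)^2, p(t-1), p(t-1)^2] with
    p(-1) = 0, giving 24 columns; WM and CSF mean series; a standardized
    linear trend; and one one-hot column per scrubbed volume. Column count is
    27 + #scrubbed.
    """
    motion = np.asarray(motion, dtype=float)
    wm = np.asarray(wm, dtype=float)
    csf = np.asarray(csf, dtype=float)
    n = motion.shape[0]
    if wm.shape[0] != n or csf.shape[0] != n:
        raise ValueError("motion, WM and CSF series must have equal length")
    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    cols = [motion, motion**2, lagged, lagged**2]
    names = (
        [f"motion_{i}" for i in range(6)]
        + [f"motion_sq_{i}" for i in range(6)]
        + [f"motion_lag_{i}" for i in range(6)]
        + [f"motion_lag_sq_{i}" for i in range(6)]
    )
    design = np.column_stack(cols + [wm, csf])
    names += ["wm", "csf"]
    trend = np.arange(n, dtype=float)
    trend = (trend - trend.mean()) / (trend.std() if n > 1 else 1.0)
    design = np.column_stack([design, trend])
    names.append("trend")
    for idx in sorted(scrubbed or ()):
        spike = np.zeros(n)
        spike[idx] = 1.0
        design = np.column_stack([design, spike])
        names.append(f"spike_{idx}")
    return NuisanceDesign(names=tuple(names), values=design)


def preprocess_report(motion: np.ndarray, fd_threshold_mm: float = FD_SCRUB_THRESHOLD_MM) -> PreprocReport:
    """Motion QC summary for one subject: FD series, scrub set, exclusion flag."""
    fd = framewise_displacement(motion)
    excluded, reason = qc_exclude(motion)
    return PreprocReport(
        fd_series=fd,
        scrubbed_volumes=tuple(sorted(scrub_mask(fd, fd_threshold_mm))),
        excluded=excluded,
        reason=reason,
        params_used={
            "max_translation_mm": MAX_TRANSLATION_MM,
            "max_rotation_deg": MAX_ROTATION_DEG,
            "fd_threshold_mm": fd_threshold_mm,
            "fd_radius_mm": FD_SPHERE_RADIUS_MM,
        },
    )


def _drop_dependent_columns(X: np.ndarray, names: tuple[str, ...]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Drop columns that do not increase matrix rank, keeping earlier ones."""
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        logger.warning("dropping rank-deficient nuisance columns: %s", dropped)
    return X[:, keep], tuple(names[j] for j in keep)


def residualize(data_2d: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """Least-squares residuals of each column series against the design.

    An intercept is always included; the temporal mean of each series is
    added back so the baseline level survives (band-pass would otherwise
    remove it anyway, but keeping it makes the step idempotent and keeps
    percent-signal units interpretable downstream).
    """
    n = data_2d.shape[0]
    X = np.column_stack([np.ones(n), design.values])
    X, _ = _drop_dependent_columns(X, ("intercept",) + design.names)
    beta, *_ = np.linalg.lstsq(X, data_2d, rcond=None)
    resid = data_2d - X @ beta
    return resid + data_2d.mean(axis=0, keepdims=True)


def bandpass(data_2d: np.ndarray, tr_s: float, band_hz: tuple[float, float] = (0.01, 0.10)) -> np.ndarray:
    """Frequency-domain band-pass with hard band edges; DC (mean) retained.

    Frequencies f with band_hz[0] <= f <= band_hz[1] pass; all others except
    the zero-frequency bin are zeroed.
    """
    n = data_2d.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    keep[0] = True  # retain baseline level
    spectrum = np.fft.rfft(data_2d, axis=0)
    spectrum[~keep] = 0.0
    return np.fft.irfft(spectrum, n=n, axis=0)


def smooth_volume(data_4d: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """3D Gaussian smoothing of every frame; FWHM given in mm."""
    if fwhm_mm <= 0:
        return data_4d
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(data_4d, sigma=(sigma, sigma, sigma, 0.0), mode="reflect")


def regress_filter_smooth(
    bold: VolumeSeries,
    design: NuisanceDesign,
    band_hz: tuple[float, float] = (0.01, 0.10),
    fwhm_mm: float = 4.0,
) -> VolumeSeries:
    """Nuisance regression, then band-pass, then spatial smoothing.

    Shape is unchanged; no volumes are deleted (scrubbed volumes are absorbed
    by their spike regressors), so every subject keeps the same number of
    time points.
    """
    if design.values.shape[0] != bold.n_volumes:
        raise ValueError("design rows must equal number of volumes")
    shape = bold.data.shape
    flat = bold.data.reshape(-1, shape[-1]).T  # (T, voxels)
    flat = residualize(flat, design)
    flat = bandpass(flat, bold.tr_s, band_hz)
    out = flat.T.reshape(shape)
    out = smooth_volume(out, fwhm_mm, bold.voxel_size_mm)
    return VolumeSeries(data=out, voxel_size_mm=bold.voxel_size_mm, tr_s=bold.tr_s)


def tissue_series(bold: VolumeSeries, mask: np.ndarray) -> np.ndarray:
    """Mean series over a tissue mask (WM or CSF proxy)."""
    if not mask.any():
        raise ValueError("empty tissue mask")
    return bold.data[mask].mean(axis=0)
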