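"""Synthetic emotional Go/NoGo BOLD cohorts with known ground truth.

Generates cohorts of bipolar-disorder (BD) mood-state subgroups (remission,
depression, mania) and healthy controls (HC) on a shared voxel grid, with
group activation differences injected into designated atlas regions. Every
downstream stage (preprocessing, GLM, random-field cluster inference,
fold-specific feature construction, classification, clinical regression) is
testable against the recorded :class:`GroundTruth` without any external data.

Signal model per voxel v in region r at volume t:

    BOLD(v, t) = B * (1 + sum_c a(r, c) / 100 * x_c(t)) + e(v, t)

where B is a baseline of 100 (so amplitudes a are percent signal change),
x_c is the HRF-convolved boxcar of condition c, and e is AR(1) Gaussian
noise in time, spatially smoothed per frame to emulate the smoothness real
BOLD noise carries (which random-field inference relies on). BD subgroups
differ from HC only by ``effect_size`` added to the Go amplitude inside
``effect_rois``; every subject additionally carries a random Go-amplitude
deviation in those regions, which is what the simulated clinical scores are
linearly coupled to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .hrf import convolve_events
from .util import derive_seed

GROUPS = ("remission", "depression", "mania", "HC")
BD_GROUPS = ("remission", "depression", "mania")

#: Cohort sizes of the study population this simulator stands in for.
DEFAULT_GROUP_SIZES = {"remission": 15, "depression": 11, "mania": 17, "HC": 43}

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort; ``seed`` fully determines output.

    Amplitudes (``base_activation``, ``effect_size``, ``subject_amp_sd``) are
    percent signal change against a baseline of 100; ``noise_sd`` is the
    AR(1) innovation standard deviation in the same units.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes: int = 307
    n_regions: int = 12
    conditions: tuple[str, ...] = ("Go", "NoGo", "Neutral")
    n_events_per_condition: int = 20
    event_duration_s: float = 1.0
    effect_rois: tuple[str, ...] = ("region_01", "region_02", "region_03")
    effect_size: float = 0.8
    noise_sd: float = 1.0
    ar_coeff: float = 0.3
    spatial_fwhm_mm: float = 6.0
    motion_spike_prob: float = 0.02
    seed: int = 0
    # secondary knobs with conventional defaults
    baseline: float = 100.0
    base_activation: float = 0.5
    subject_amp_sd: float = 0.25
    clinical_metrics: tuple[str, ...] = ("psqi", "stroop1", "tmtb", "go_omission")
    clinical_links: tuple[tuple[str, str, float], ...] = (("region_01", "stroop1", -0.6),)

    def __post_init__(self):
        if any(s < 3 for s in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 3 (interior plus background shell)")
        if not (-1.0 < self.ar_coeff < 1.0):
            raise ValueError("ar_coeff must lie in (-1, 1)")
        if not (0.0 <= self.motion_spike_prob <= 1.0):
            raise ValueError("motion_spike_prob must be a probability")
        min_vols = 2 * self.n_events_per_condition * math.ceil(
            self.event_duration_s / self.tr_s
        )
        if self.n_volumes < min_vols:
            raise ValueError(
                f"n_volumes={self.n_volumes} too small for "
                f"{self.n_events_per_condition} events per condition "
                f"(need >= {min_vols})"
            )
        unknown = set(self.clinical_metrics) - set(self.clinical_metrics)
        for region, metric, r in self.clinical_links:
            if metric not in self.clinical_metrics:
                raise ValueError(f"clinical link metric {metric!r} not in clinical_metrics")
            if not (-1.0 <= r <= 1.0):
                raise ValueError("clinical link slope must be a correlation in [-1, 1]")
        del unknown


@dataclass(frozen=True)
class Atlas:
    """Integer-labeled parcellation: 0 = background, 1..R = regions."""

    labels: np.ndarray
    names: tuple[str, ...]
    voxel_size_mm: float

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def wm_mask(self) -> np.ndarray:
        """Designated 'white matter' proxy: lower-corner block of the shell."""
        return _shell_corner(self.labels, lower=True)

    @property
    def csf_mask(self) -> np.ndarray:
        """Designated 'CSF' proxy: upper-corner block of the shell."""
        return _shell_corner(self.labels, lower=False)


def _shell_corner(labels: np.ndarray, lower: bool) -> np.ndarray:
    mask = np.zeros(labels.shape, dtype=bool)
    nx, ny, nz = labels.shape
    k = max(1, min(nx, ny, nz) // 4)
    if lower:
        mask[:k, :k, :k] = True
    else:
        mask[-k:, -k:, -k:] = True
    return mask & (labels == 0)


@dataclass(frozen=True)
class VolumeSeries:
    """One subject's 4D BOLD grid (x, y, z, t) with geometry and TR."""

    data: np.ndarray
    voxel_size_mm: float
    tr_s: float

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    group: str
    bold: VolumeSeries
    events: pd.DataFrame
    motion: np.ndarray
    clinical: dict[str, float]


@dataclass(frozen=True)
class GroundTruth:
    """Injected effects, recoverable from (config, seed) for recovery tests."""

    effect_rois: tuple[str, ...]
    amplitudes: dict[tuple[str, str, str], float]  # (region, condition, group) -> %PSC
    clinical_link: tuple[tuple[str, str, float], ...]
    subject_go_deviation: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Atlas construction


def _partition_box(box: tuple[slice, slice, slice], n: int) -> list[tuple[slice, slice, slice]]:
    """Recursively split a box into n connected sub-boxes of balanced volume."""
    if n == 1:
        return [box]
    lengths = [s.stop - s.start for s in box]
    axis = int(np.argmax(lengths))
    if lengths[axis] < 2:
        raise ValueError(
            f"grid too small: cannot split a box of shape {tuple(lengths)} "
            f"into {n} regions"
        )
    n1 = n // 2
    n2 = n - n1
    cut = box[axis].start + max(1, min(lengths[axis] - 1, round(lengths[axis] * n1 / n)))
    left = list(box)
    right = list(box)
    left[axis] = slice(box[axis].start, cut)
    right[axis] = slice(cut, box[axis].stop)
    return _partition_box(tuple(left), n1) + _partition_box(tuple(right), n2)


def make_atlas(config: SimConfig) -> Atlas:
    """Deterministic toy parcellation of the grid interior.

    The one-voxel background shell is retained (label 0); the interior is
    tiled by ``n_regions`` disjoint connected boxes. A degenerate request
    (regions than the interior cannot host) raises a sizing error.
    """
    if config.n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    shape = tuple(config.grid_shape)
    interior = tuple(slice(1, s - 1) for s in shape)
    n_interior = int(np.prod([s.stop - s.start for s in interior]))
    if n_interior < config.n_regions:
        raise ValueError(
            f"grid interior has {n_interior} voxels, fewer than "
            f"n_regions={config.n_regions}"
        )
    labels = np.zeros(shape, dtype=np.int32)
    for i, box in enumerate(_partition_box(interior, config.n_regions), start=1):
        labels[box] = i
    names = tuple(f"region_{i:02d}" for i in range(1, config.n_regions + 1))
    return Atlas(labels=labels, names=names, voxel_size_mm=config.voxel_size_mm)


# ---------------------------------------------------------------------------
# Event schedule


def make_event_schedule(config: SimConfig) -> pd.DataFrame:
    """Pseudo-randomized non-overlapping event schedule, identical across subjects.

    The sequence interleaves conditions in shuffled blocks (each block one
    event of every condition) and jitters onsets inside equal slots, so no
    two events overlap and onsets need not align to volume boundaries. The
    schedule is a function of the config only — all subjects of a cohort see
    the same trial sequence and timing.
    """
    if not config.conditions:
        raise ValueError("conditions must be nonempty")
    rng = np.random.default_rng(derive_seed(config.seed, "events"))
    n_total = len(config.conditions) * config.n_events_per_condition
    scan_s = config.n_volumes * config.tr_s
    usable_s = scan_s - config.event_duration_s
    slot = usable_s / n_total
    if slot <= config.event_duration_s:
        raise ValueError(
            f"cannot schedule {n_total} events of {config.event_duration_s}s "
            f"in a {scan_s}s scan without overlap"
        )
    order: list[str] = []
    for _ in range(config.n_events_per_condition):
        block = list(config.conditions)
        rng.shuffle(block)
        order.extend(block)
    jitter = rng.uniform(0.0, slot - config.event_duration_s, size=n_total)
    onsets = np.arange(n_total) * slot + jitter
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.full(n_total, config.event_duration_s),
            "condition": order,
        }
    )


def condition_regressors(
    events: pd.DataFrame, conditions: tuple[str, ...], tr_s: float, n_volumes: int
) -> np.ndarray:
    """(n_volumes, n_conditions) matrix of HRF-convolved condition boxcars."""
    cols = []
    for cond in conditions:
        sel = events[events["condition"] == cond]
        if sel.empty:
            cols.append(np.zeros(n_volumes))
        else:
            cols.append(
                convolve_events(
                    sel["onset"].to_numpy(), sel["duration"].to_numpy(), tr_s, n_volumes
                )
            )
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Subjects


def _group_amplitudes(config: SimConfig) -> dict[tuple[str, str, str], float]:
    amps: dict[tuple[str, str, str], float] = {}
    names = tuple(f"region_{i:02d}" for i in range(1, config.n_regions + 1))
    for region in names:
        for cond in config.conditions:
            for group in GROUPS:
                a = config.base_activation
                if cond == "Go" and region in config.effect_rois and group != "HC":
                    a += config.effect_size
                amps[(region, cond, group)] = a
    return amps


def _ar1_noise(rng: np.random.Generator, shape_xyz, n_volumes, sd, phi) -> np.ndarray:
    innov_sd = sd * math.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(shape_xyz + (n_volumes,))
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0] * sd
    for t in range(1, n_volumes):
        out[..., t] = phi * out[..., t - 1] + innov_sd * eps[..., t]
    return out


def _motion_trace(rng: np.random.Generator, n_volumes: int, spike_prob: float) -> np.ndarray:
    """Smooth small drift plus occasional spikes; translations mm, rotations rad."""
    steps = rng.standard_normal((n_volumes, 6))
    steps[:, :3] *= 0.01  # mm per volume
    steps[:, 3:] *= 0.0002  # rad per volume
    trace = np.cumsum(steps, axis=0)
    spikes = rng.random(n_volumes) < spike_prob
    spikes[0] = False
    for t in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)
        trace[t, axis] += 0.5 * rng.choice([-1.0, 1.0])
    return trace


def simulate_subject(
    config: SimConfig, atlas: Atlas, group: str, id: str
) -> tuple[SubjectRecord, float]:
    """One subject's BOLD, events, motion and clinical scores.

    Returns the record and the subject's Go-amplitude deviation (the latent
    value the clinical link couples to). Reproducible from (config, id).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(derive_seed(config.seed, f"subject:{id}"))
    events = make_event_schedule(config)
    regs = condition_regressors(events, config.conditions, config.tr_s, config.n_volumes)
    amps = _group_amplitudes(config)

    dev = float(rng.normal(0.0, config.subject_amp_sd))
    shape = tuple(config.grid_shape)
    amp_vol = np.zeros(shape + (len(config.conditions),))
    for lab, region in enumerate(atlas.names, start=1):
        mask = atlas.labels == lab
        for c, cond in enumerate(config.conditions):
            a = amps[(region, cond, group)]
            if cond == "Go" and region in config.effect_rois:
                a += dev
            amp_vol[mask, c] = a

    signal = config.baseline * (
        1.0 + np.einsum("xyzc,tc->xyzt", amp_vol, regs) / 100.0
    )
    noise = _ar1_noise(rng, shape, config.n_volumes, config.noise_sd, config.ar_coeff)
    if config.spatial_fwhm_mm > 0:
        sigma_vox = config.spatial_fwhm_mm * FWHM_TO_SIGMA / config.voxel_size_mm
        ndimage.gaussian_filter(noise, sigma=(sigma_vox,) * 3 + (0.0,), output=noise, mode="wrap")
        # smoothing shrinks variance; restore the requested marginal sd
        std = noise.std()
        if std > 0:
            noise *= config.noise_sd / std
    bold = VolumeSeries(
        data=signal + noise, voxel_size_mm=config.voxel_size_mm, tr_s=config.tr_s
    )
    motion = _motion_trace(rng, config.n_volumes, config.motion_spike_prob)

    linked = {metric: (region, r) for region, metric, r in config.clinical_links}
    clinical: dict[str, float] = {}
    for metric in config.clinical_metrics:
        if metric in linked and config.subject_amp_sd > 0:
            _, r = linked[metric]
            z = dev / config.subject_amp_sd
            clinical[metric] = r * z + math.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal()
        else:
            clinical[metric] = float(rng.standard_normal())
    record = SubjectRecord(
        id=id, group=group, bold=bold, events=events, motion=motion, clinical=clinical
    )
    return record, dev


def simulate_cohort(
    config: SimConfig, group_sizes: dict[str, int] | None = None
) -> tuple[list[SubjectRecord], GroundTruth, Atlas]:
    """Generate a full cohort plus its ground truth and atlas.

    Default group sizes match the study population this simulator emulates
    (15 remission + 11 depression + 17 mania BD and 43 HC). The cohort is a
    pure function of (config, group_sizes).
    """
    sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    for group, n in sizes.items():
        if group not in GROUPS:
            raise ValueError(f"unknown group label {group!r}")
        if n < 1:
            raise ValueError(f"group {group!r} needs at least one subject")
    atlas = make_atlas(config)
    subjects: list[SubjectRecord] = []
    devs: dict[str, float] = {}
    for group in GROUPS:
        for i in range(sizes.get(group, 0)):
            sid = f"{group}_{i:02d}"
            rec, dev = simulate_subject(config, atlas, group, sid)
            subjects.append(rec)
            devs[sid] = dev
    truth = GroundTruth(
        effect_rois=tuple(config.effect_rois),
        amplitudes=_group_amplitudes(config),
        clinical_link=tuple(config.clinical_links),
        subject_go_deviation=devs,
    )
    return subjects, truth, atlas


def null_config(config: SimConfig) -> SimConfig:
    """The same study conditions with the group effect removed (null cohort)."""
    return replace(config, effect_size=0.0)
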