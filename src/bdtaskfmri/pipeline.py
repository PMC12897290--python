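"""End-to-end orchestration: simulate -> preprocess -> GLM -> nested CV.

``RunConfig`` aggregates every pipeline threshold with the analysis defaults
(voxel p 0.001, cluster p 0.05, minimum extent 10 voxels, FD scrub threshold
0.2 mm, outer 5 / inner 3 folds, 10,000 bootstrap resamples); all are
overridable. A single master seed governs cohort generation, fold splits,
classifier randomness, bootstrap resampling and Shapley sampling via
stage-tagged seed derivation, so one (config, seed) pair reproduces every
result table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, clinical, glm, preprocess
from .simulate import (
    Atlas,
    BD_GROUPS,
    SimConfig,
    SubjectRecord,
    simulate_cohort,
)
from .util import derive_seed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    group_sizes: dict | None = None
    contrasts: tuple[str, ...] = tuple(glm.CONTRASTS)
    classifiers: tuple[str, ...] = classify.CLASSIFIER_FAMILIES
    mood_state: str = "remission"
    n_outer: int = 5
    n_inner: int = 3
    n_boot: int = 10000
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    min_extent: int = 10
    fd_threshold_mm: float = 0.2
    band_hz: tuple[float, float] = (0.01, 0.10)
    smooth_fwhm_mm: float = 4.0
    compute_shap: bool = True
    seed: int = 0

    def __post_init__(self):
        for c in self.contrasts:
            if c not in glm.CONTRASTS:
                raise ValueError(f"unknown contrast {c!r}; expected one of {list(glm.CONTRASTS)}")
        for f in self.classifiers:
            if f not in classify.CLASSIFIER_FAMILIES:
                raise ValueError(f"unknown classifier {f!r}")
        if self.mood_state not in BD_GROUPS:
            raise ValueError(f"mood_state must be one of {BD_GROUPS}")

    @property
    def rft_params(self) -> dict:
        return {
            "voxel_p": self.voxel_p,
            "cluster_p": self.cluster_p,
            "min_extent": self.min_extent,
        }

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def preprocess_subject(
    record: SubjectRecord, atlas: Atlas, config: RunConfig
) -> tuple[SubjectRecord | None, preprocess.PreprocReport]:
    """Motion QC, scrubbing, nuisance regression, filtering, smoothing.

    Returns (preprocessed record, report); the record is None when the
    subject fails the gross-motion exclusion rule.
    """
    report = preprocess.preprocess_report(record.motion, config.fd_threshold_mm)
    if report.excluded:
        logger.info("subject %s excluded: %s", record.id, report.reason)
        return None, report
    wm = preprocess.tissue_series(record.bold, atlas.wm_mask)
    csf = preprocess.tissue_series(record.bold, atlas.csf_mask)
    design = preprocess.build_nuisance(
        record.motion, wm, csf, set(report.scrubbed_volumes)
    )
    clean = preprocess.regress_filter_smooth(
        record.bold, design, band_hz=config.band_hz, fwhm_mm=config.smooth_fwhm_mm
    )
    return dataclasses.replace(record, bold=clean), report


def prepare_cohort(
    subjects: list[SubjectRecord],
    atlas: Atlas,
    config: RunConfig,
    patient_groups: tuple[str, ...],
) -> tuple[classify.PreparedCohort, pd.DataFrame]:
    """Preprocess every subject and fit all first-level contrast z-maps.

    Both steps are strictly per-subject, so running them once for the whole
    cohort cannot leak information across cross-validation folds. Returns the
    prepared cohort (QC-passing subjects only) and the QC table.
    """
    qc_rows = []
    zmaps: dict[tuple[str, str], glm.StatMap] = {}
    bold: dict[str, object] = {}
    groups: dict[str, str] = {}
    labels: dict[str, int] = {}
    ids: list[str] = []
    for rec in subjects:
        clean, report = preprocess_subject(rec, atlas, config)
        qc_rows.append(
            {
                "id": rec.id,
                "group": rec.group,
                "max_fd_mm": float(report.fd_series.max()),
                "n_scrubbed": len(report.scrubbed_volumes),
                "excluded": report.excluded,
                "reason": report.reason,
            }
        )
        if clean is None:
            continue
        design = glm.first_level_design(
            clean.events, clean.bold.tr_s, clean.bold.n_volumes
        )
        for cname in config.contrasts:
            spec = glm.ContrastSpec.canonical(cname)
            zmaps[(rec.id, cname)] = glm.first_level_zmap(clean.bold, design, spec)
        bold[rec.id] = clean.bold
        groups[rec.id] = rec.group
        labels[rec.id] = 0 if rec.group == "HC" else 1
        ids.append(rec.id)
    prepared = classify.PreparedCohort(
        ids=tuple(ids),
        groups=groups,
        labels=labels,
        zmaps=zmaps,
        bold=bold,
        atlas=atlas,
    )
    return prepared, pd.DataFrame(qc_rows)


def _subset(prepared: classify.PreparedCohort, keep_groups: tuple[str, ...]) -> classify.PreparedCohort:
    ids = tuple(s for s in prepared.ids if prepared.groups[s] in keep_groups)
    return classify.PreparedCohort(
        ids=ids,
        groups={s: prepared.groups[s] for s in ids},
        labels={s: prepared.labels[s] for s in ids},
        zmaps={k: v for k, v in prepared.zmaps.items() if k[0] in ids},
        bold={s: prepared.bold[s] for s in ids},
        atlas=prepared.atlas,
    )


def _report_rows(reports: list[classify.EvaluationReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        m = rep.metrics
        rows.append(
            {
                "contrast": rep.contrast,
                "classifier": rep.classifier,
                "accuracy": m["accuracy"],
                "sensitivity": m["sensitivity"],
                "specificity": m["specificity"],
                "auc": m["auc"],
                "f1": m["f1"],
                "ppv": m["ppv"],
                "npv": m["npv"],
                "fdr": m["fdr"],
                "auc_ci_low": rep.bootstrap["auc_ci"][0],
                "auc_ci_high": rep.bootstrap["auc_ci"][1],
                "accuracy_ci_low": rep.bootstrap["accuracy_ci"][0],
                "accuracy_ci_high": rep.bootstrap["accuracy_ci"][1],
                "skipped_folds": rep.skipped_folds,
            }
        )
    return pd.DataFrame(rows)


def run_state_specific(
    config: RunConfig,
    prepared: classify.PreparedCohort | None = None,
) -> tuple[pd.DataFrame, list[classify.EvaluationReport]]:
    """Mood-state subgroup vs HC classification over all (contrast, classifier).

    When ``prepared`` is omitted the cohort is simulated from ``config.sim``.
    Returns the results table (one row per contrast x classifier, mirroring
    the per-condition evaluation layout) and the full per-run reports.
    """
    if prepared is None:
        subjects, _, atlas = simulate_cohort(config.sim, config.group_sizes)
        prepared, _ = prepare_cohort(subjects, atlas, config, BD_GROUPS)
    cohort = _subset(prepared, (config.mood_state, "HC"))
    plan = classify.make_fold_plan(
        cohort.labels, derive_seed(config.seed, "folds"), config.n_outer, config.n_inner
    )
    reports = []
    for cname in config.contrasts:
        for family in config.classifiers:
            rep = classify.run_nested_cv(
                cohort,
                cname,
                classify.ClassifierSpec(family=family),
                plan,
                rft_params=config.rft_params,
                compute_shap=config.compute_shap,
                n_boot=config.n_boot,
            )
            reports.append(rep)
    return _report_rows(reports), reports


def run_pooled_generalization(
    config: RunConfig,
    prepared: classify.PreparedCohort | None = None,
) -> tuple[pd.DataFrame, list[classify.EvaluationReport], dict]:
    """Pooled BD (all mood states) vs HC, ROIs sourced from one state's TRAIN.

    Abnormal ROIs are defined per fold from ``config.mood_state`` TRAIN
    patients plus TRAIN controls, then applied to all pooled TRAIN/TEST
    subjects; leakage constraints are identical to the state-specific mode.
    The manifest records which state sourced the ROIs.
    """
    if prepared is None:
        subjects, _, atlas = simulate_cohort(config.sim, config.group_sizes)
        prepared, _ = prepare_cohort(subjects, atlas, config, BD_GROUPS)
    present = set(prepared.groups.values())
    missing = [g for g in BD_GROUPS if g not in present]
    if missing:
        raise ValueError(f"pooled generalization needs all BD subgroups; missing {missing}")
    plan = classify.make_fold_plan(
        prepared.labels, derive_seed(config.seed, "folds:pooled"), config.n_outer, config.n_inner
    )
    reports = []
    for cname in config.contrasts:
        for family in config.classifiers:
            rep = classify.run_nested_cv(
                prepared,
                cname,
                classify.ClassifierSpec(family=family),
                plan,
                rft_params=config.rft_params,
                roi_state=config.mood_state,
                compute_shap=config.compute_shap,
                n_boot=config.n_boot,
            )
            reports.append(rep)
    manifest = {
        "mode": "pooled_generalization",
        "roi_source_state": config.mood_state,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    return _report_rows(reports), reports, manifest


def run_clinical_associations(
    prepared: classify.PreparedCohort,
    clinical_scores: dict[str, dict[str, float]],
    config: RunConfig,
    contrast: str,
) -> list[clinical.AssociationResult]:
    """Per-group (patients, controls) brain-behavior association blocks."""
    results = []
    for group_name, label in (("BD", 1), ("HC", 0)):
        ids = [s for s in prepared.ids if prepared.labels[s] == label]
        maps = [prepared.zmaps[(s, contrast)] for s in ids]
        metric_names = sorted(next(iter(clinical_scores.values())))
        metrics = {
            m: np.array([clinical_scores[s][m] for s in ids]) for m in metric_names
        }
        results.append(
            clinical.associate(
                maps,
                metrics,
                prepared.atlas,
                block=(contrast, config.mood_state, group_name),
                voxel_p=config.voxel_p,
                cluster_p=config.cluster_p,
                min_extent=config.min_extent,
            )
        )
    return results


def write_results(
    outdir: str | Path,
    table: pd.DataFrame,
    config: RunConfig,
    manifest_extra: dict | None = None,
) -> Path:
    """Write the results table plus a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "results.tsv", sep="\t", index=False, float_format="%.6f")
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "mood_state": config.mood_state,
        "contrasts": list(config.contrasts),
        "classifiers": list(config.classifiers),
    }
    manifest.update(manifest_extra or {})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir / "results.tsv"
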