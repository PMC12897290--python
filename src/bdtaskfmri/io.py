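"""On-disk interchange: NIfTI volumes, tab-separated tables, YAML configs.

Each simulated subject is written as a 4D NIfTI plus tab-separated events
(onset, duration, condition) and 6-column motion files; the cohort gets one
subjects table (id, group, clinical columns); the atlas a 3D NIfTI plus a
name lookup table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .simulate import Atlas, SimConfig, SubjectRecord, VolumeSeries


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_volume(series: VolumeSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_size_mm))
    img.header.set_zooms((series.voxel_size_mm,) * 3 + (series.tr_s,))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> VolumeSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return VolumeSeries(
        data=np.asarray(img.dataobj, dtype=float),
        voxel_size_mm=float(zooms[0]),
        tr_s=float(zooms[3]) if len(zooms) > 3 else 1.0,
    )


def write_atlas(atlas: Atlas, nifti_path: str | Path, lookup_path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size_mm)),
        str(nifti_path),
    )
    pd.DataFrame({"label": range(1, atlas.n_regions + 1), "name": atlas.names}).to_csv(
        lookup_path, sep="\t", index=False
    )


def read_atlas(nifti_path: str | Path, lookup_path: str | Path) -> Atlas:
    img = nib.load(str(nifti_path))
    lut = pd.read_csv(lookup_path, sep="\t").sort_values("label")
    return Atlas(
        labels=np.asarray(img.dataobj, dtype=np.int32),
        names=tuple(lut["name"]),
        voxel_size_mm=float(img.header.get_zooms()[0]),
    )


def write_subject(record: SubjectRecord, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(record.bold, outdir / f"{record.id}_bold.nii.gz")
    record.events.to_csv(outdir / f"{record.id}_events.tsv", sep="\t", index=False)
    np.savetxt(outdir / f"{record.id}_motion.tsv", record.motion, delimiter="\t")


def write_cohort(
    subjects: list[SubjectRecord], atlas: Atlas, config: SimConfig, outdir: str | Path
) -> Path:
    """Write the full cohort (per-subject files, atlas, subjects table, config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in subjects:
        write_subject(rec, outdir / "subjects")
        rows.append({"id": rec.id, "group": rec.group, **rec.clinical})
    pd.DataFrame(rows).to_csv(outdir / "participants.tsv", sep="\t", index=False)
    write_atlas(atlas, outdir / "atlas.nii.gz", outdir / "atlas_lookup.tsv")
    write_sim_config(config, outdir / "sim_config.yaml")
    return outdir


def write_sim_config(config: SimConfig, path: str | Path) -> None:
    payload = dataclasses.asdict(config)
    payload["clinical_links"] = [list(l) for l in payload["clinical_links"]]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_sim_config(path: str | Path) -> SimConfig:
    payload = yaml.safe_load(Path(path).read_text())
    for key in ("grid_shape", "conditions", "effect_rois", "clinical_metrics"):
        if key in payload:
            payload[key] = tuple(payload[key])
    if "clinical_links" in payload:
        payload["clinical_links"] = tuple(tuple(l) for l in payload["clinical_links"])
    return SimConfig(**payload)
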