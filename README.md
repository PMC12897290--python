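# bdtaskfmri

Leakage-controlled task-fMRI analysis pipeline for case-control
classification, modeled on an emotional Go/NoGo study design: synthetic BOLD
cohorts, motion QC and nuisance preprocessing, per-contrast GLM z-maps,
Gaussian-random-field (GRF) cluster correction, fold-specific abnormal-ROI
time-series features, nested cross-validated classification with bootstrap
confidence intervals and Shapley ROI importance, and GRF-corrected
brain-behavior association with Benjamini-Hochberg FDR.

## The scientific problem

Task-fMRI case-control studies often (a) locate group-difference clusters
with random-field-corrected statistics, (b) extract features from those
"abnormal" regions, and (c) train classifiers on the features. Done naively,
step (a) sees the full cohort — including the subjects later used to test the
classifier — and the reported accuracy is inflated by feature-selection
leakage. This package implements the full chain with the leakage surfaces
closed: within every outer cross-validation fold, the abnormal-ROI
definition, the time-series truncation length, the feature scaler and the
hyperparameters are functions of the training subjects alone. A built-in
permuted-label experiment verifies that the pipeline delivers chance AUC
when there is nothing to find.

Real clinical cohorts for this design are private, so the package ships a
synthetic BOLD generator with planted, known ground truth (effect regions,
per-subject amplitudes, clinical-score links), making every downstream claim
checkable: calibration of the GRF correction, recovery of planted effects,
recovery of planted brain-behavior correlations.

## Worked example

```python
from bdtaskfmri import pipeline
from bdtaskfmri.simulate import SimConfig, simulate_cohort

sim = SimConfig(
    grid_shape=(16, 16, 16), n_volumes=100, n_regions=8,
    n_events_per_condition=10,
    effect_rois=("region_01", "region_02", "region_03"),
    effect_size=3.0, seed=7,
)
config = pipeline.RunConfig(
    sim=sim, contrasts=("Go-NoGo",),
    classifiers=("random_forest", "logistic_regression"),
    n_boot=2000, seed=7,
)
subjects, truth, atlas = simulate_cohort(sim, {"remission": 10, "HC": 10})
prepared, qc = pipeline.prepare_cohort(subjects, atlas, config, ("remission",))
table, reports = pipeline.run_state_specific(config, prepared)
print(table[["contrast", "classifier", "accuracy", "auc",
             "auc_ci_low", "auc_ci_high", "skipped_folds"]].to_string(index=False))
print(reports[0].importance.top(3).to_string(index=False))
```

Output (deterministic for this config and seed):

```
contrast          classifier  accuracy   auc  auc_ci_low  auc_ci_high  skipped_folds
 Go-NoGo       random_forest     100.0 100.0         1.0          1.0              0
 Go-NoGo logistic_regression     100.0 100.0         1.0          1.0              0
      roi     share  mean_abs_mass  folds_present
region_01 34.828630       0.178875              5
region_02 30.661073       0.157687              5
region_03 28.504729       0.146625              5
```

The three planted effect regions are recovered as the abnormal ROI set in
every fold and carry essentially all the attribution mass; with a strong
planted effect the nested pipeline separates the groups perfectly.

## Command line

```bash
bdtaskfmri simulate-cohort --out cohort/ --seed 1 --group-sizes '{"remission": 4, "HC": 4}'
bdtaskfmri run-cv --out results/ --seed 1 --contrast Go-NoGo --classifier random_forest
bdtaskfmri run-cv --out results_pooled/ --seed 1 --pooled          # BD (all states) vs HC
bdtaskfmri clinical-assoc --out assoc/ --seed 1 --contrast Go-NoGo
bdtaskfmri report --results results/results.tsv
```

`run-cv` without flags runs all six contrasts (Go-NoGo, Go+NoGo, Go-Neutral,
NoGo-Neutral, Go, NoGo) against all five classifier families on the default
cohort (43 patients across three mood states + 43 controls, 24^3 grid) —
substantial compute; narrow the flags for exploration.

## Reproduction

All randomness flows from one master seed through tagged derivation, so any
run is reproducible bit-for-bit from (config, seed) — including the 10,000
bootstrap resamples behind the confidence intervals.

The acceptance script runs the pipeline's self-validation experiments (GRF
null calibration, smoothness recovery, planted-effect recovery, permuted-
label leakage guard, separability sanity, clinical-link recovery) and writes
the key quantities as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the statistical model, parameter defaults, the
generator's known realism limits, and numerical choices.

## Layout

- `src/bdtaskfmri/simulate.py` — synthetic cohort generator (atlas, events, BOLD, motion, clinical scores)
- `src/bdtaskfmri/preprocess.py` — FD, QC exclusion, scrubbing, Friston-24 nuisance, band-pass, smoothing
- `src/bdtaskfmri/glm.py` — first/second-level GLM, t-to-z, six canonical contrasts
- `src/bdtaskfmri/rft.py` — smoothness estimation, 18-connectivity clusters, GRF cluster p-values
- `src/bdtaskfmri/features.py` — fold-internal abnormal ROIs and leakage-free feature matrices
- `src/bdtaskfmri/classify.py` — nested CV, five classifier families, metrics, bootstrap CIs
- `src/bdtaskfmri/explain.py`, `shapley.py` — exact linear + permutation-sampling Shapley, ROI shares
- `src/bdtaskfmri/clinical.py` — voxelwise metric regression, cluster fits, BH-FDR
- `src/bdtaskfmri/pipeline.py` — orchestration, run configs, result tables, manifests
- `src/bdtaskfmri/validation.py` — self-validation experiments behind the acceptance script
- `src/bdtaskfmri/io.py`, `cli.py` — NIfTI/TSV/YAML interchange and the `bdtaskfmri` CLI
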