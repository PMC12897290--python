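"""Nested stratified cross-validation, classifiers, metrics, bootstrap CIs.

Evaluation is leakage-controlled: within each outer fold, abnormal-ROI
definition, T_use selection, feature scaling, hyperparameter tuning (inner
3-fold grid search maximizing AUC) and model fitting all see TRAIN subjects
only, and pooled out-of-fold TEST predictions feed every reported metric.
Folds whose TRAIN z-map yields no abnormal ROI (K = 0) are skipped and
counted, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import explain, features, glm
from .simulate import Atlas, VolumeSeries
from .util import derive_seed

logger = logging.getLogger(__name__)

#: Default hyperparameter grids per family. The grids are configuration, not
#: fidelity claims; each is deliberately small and overridable.
DEFAULT_GRIDS: dict[str, dict] = {
    "logistic_regression": {"C": [0.01, 0.1, 1.0]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "random_forest": {"max_depth": [None, 4]},
    "xgboost": {"max_depth": [2, 4], "learning_rate": [0.1, 0.3]},
    "naive_bayes": {"var_smoothing": [1e-9, 1e-6, 1e-3]},
}

CLASSIFIER_FAMILIES = tuple(DEFAULT_GRIDS)


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    grid: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(
                f"unknown classifier family {self.family!r}; expected one of "
                f"{CLASSIFIER_FAMILIES}"
            )
        if not self.grid:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.family])

    def make_estimator(self, seed: int):
        if self.family == "logistic_regression":
            return LogisticRegression(max_iter=5000)
        if self.family == "svm":
            return SVC(kernel="linear")
        if self.family == "random_forest":
            return RandomForestClassifier(n_estimators=100, random_state=seed)
        if self.family == "xgboost":
            return XGBClassifier(
                n_estimators=50,
                verbosity=0,
                random_state=seed,
                eval_metric="logloss",
                n_jobs=1,
            )
        return GaussianNB()


@dataclass(frozen=True)
class FoldPlan:
    """Outer 5-fold / inner 3-fold stratified split plan over subject ids."""

    outer: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, test) per fold
    n_inner: int
    seed: int


def make_fold_plan(
    labels: dict[str, int], seed: int, n_outer: int = 5, n_inner: int = 3
) -> FoldPlan:
    """Stratified outer folds over subject ids; reproducible from the seed.

    Outer test sets partition the cohort and preserve the class ratio within
    one subject per fold (stratification).
    """
    ids = np.array(sorted(labels))
    y = np.array([labels[s] for s in ids])
    for cls in np.unique(y):
        if (y == cls).sum() < n_outer:
            raise ValueError(
                f"class {cls} has fewer than {n_outer} subjects; reduce the "
                "number of outer folds in the config"
            )
    skf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed % (2**31))
    outer = tuple(
        (tuple(ids[tr]), tuple(ids[te])) for tr, te in skf.split(ids.reshape(-1, 1), y)
    )
    return FoldPlan(outer=outer, n_inner=n_inner, seed=seed)


# ---------------------------------------------------------------------------
# Metrics


def compute_metrics(y_true, y_pred, scores) -> dict[str, float]:
    """Confusion-matrix metrics (percent) + rank-based AUC from pooled predictions.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); PPV = TP/(TP+FP);
    NPV = TN/(TN+FN); FDR = 1 - PPV; F1 is the harmonic mean of PPV and
    sensitivity. Undefined ratios (zero denominator) are NaN.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.size == 0:
        raise ValueError("no pooled predictions")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    ppv = ratio(tp, tp + fp)
    sens = ratio(tp, tp + fn)
    auc = (
        100.0 * roc_auc_score(y_true, scores) if len(np.unique(y_true)) == 2 else float("nan")
    )
    f1 = (
        2.0 * ppv * sens / (ppv + sens)
        if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
        else float("nan")
    )
    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": sens,
        "specificity": ratio(tn, tn + fp),
        "auc": auc,
        "f1": f1,
        "ppv": ppv,
        "npv": ratio(tn, tn + fn),
        "fdr": 100.0 - ppv if np.isfinite(ppv) else float("nan"),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }


def bootstrap_ci(
    y_true, y_pred, scores, n_boot: int = 10000, seed: int = 0
) -> dict[str, object]:
    """Percentile 95% CIs for AUC and accuracy over subject-level resamples.

    Resamples containing only one class are excluded from the AUC
    distribution (and counted); accuracy uses all resamples. Deterministic
    given the seed.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n = y_true.size
    if n == 0:
        raise ValueError("no pooled predictions to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    acc = (y_true[idx] == y_pred[idx]).mean(axis=1)
    aucs = []
    excluded = 0
    for row in idx:
        yt = y_true[row]
        if yt.min() == yt.max():
            excluded += 1
            continue
        aucs.append(roc_auc_score(yt, scores[row]))
    aucs = np.asarray(aucs)
    out = {
        "accuracy_ci": (float(np.percentile(acc, 2.5)), float(np.percentile(acc, 97.5))),
        "auc_ci": (
            (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5)))
            if aucs.size
            else (float("nan"), float("nan"))
        ),
        "n_boot": n_boot,
        "excluded_one_class": excluded,
    }
    return out


# ---------------------------------------------------------------------------
# Nested cross-validation


@dataclass(frozen=True)
class PreparedCohort:
    """Per-subject artifacts the nested CV consumes.

    ``zmaps`` maps (subject id, contrast name) to the subject's first-level
    z-map; ``bold`` maps subject id to the preprocessed series feeding ROI
    time-series features; ``groups`` maps id to mood-state/HC group label.
    """

    ids: tuple[str, ...]
    groups: dict[str, str]
    labels: dict[str, int]  # 1 = patient, 0 = control
    zmaps: dict[tuple[str, str], glm.StatMap]
    bold: dict[str, VolumeSeries]
    atlas: Atlas


@dataclass
class FoldResult:
    fold: int
    skipped: bool
    roi_names: tuple[str, ...] = ()
    k: int = 0
    t_use: int = 0
    test_ids: tuple[str, ...] = ()
    y_true: np.ndarray | None = None
    y_pred: np.ndarray | None = None
    scores: np.ndarray | None = None
    best_params: dict | None = None
    column_shap: np.ndarray | None = None
    metrics: dict | None = None


@dataclass
class EvaluationReport:
    contrast: str
    classifier: str
    metrics: dict
    folds: list[FoldResult]
    bootstrap: dict
    skipped_folds: int
    importance: "object" = None  # explain.ImportanceTable when SHAP computed


def _score(model, X) -> np.ndarray:
    """Continuous class-1 score: probability when available, else decision value."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def run_nested_cv(
    prepared: PreparedCohort,
    contrast: str,
    classifier: ClassifierSpec,
    plan: FoldPlan,
    rft_params: dict | None = None,
    roi_state: str | None = None,
    compute_shap: bool = True,
    n_boot: int = 10000,
) -> EvaluationReport:
    """Leakage-free nested CV for one (contrast, classifier) pair.

    ``roi_state`` switches to the pooled-generalization setting: abnormal
    ROIs are defined from that mood state's TRAIN patients (plus TRAIN
    controls) while the classifier is trained and evaluated on all TRAIN /
    TEST subjects of the cohort.
    """
    rft_params = rft_params or {}
    folds: list[FoldResult] = []
    pooled_true, pooled_pred, pooled_scores = [], [], []
    for f, (train_ids, test_ids) in enumerate(plan.outer):
        bd_roi_train = [
            s
            for s in train_ids
            if prepared.labels[s] == 1
            and (roi_state is None or prepared.groups[s] == roi_state)
        ]
        hc_roi_train = [s for s in train_ids if prepared.labels[s] == 0]
        rois = features.define_abnormal_rois(
            [prepared.zmaps[(s, contrast)] for s in bd_roi_train],
            [prepared.zmaps[(s, contrast)] for s in hc_roi_train],
            prepared.atlas,
            contrast,
            f,
            tuple(train_ids),
            **rft_params,
        )
        if rois.k == 0:
            logger.info("fold %d skipped: no abnormal ROIs on TRAIN", f)
            folds.append(FoldResult(fold=f, skipped=True, test_ids=tuple(test_ids)))
            continue
        matrices = {
            s: features.extract_roi_timeseries(prepared.bold[s], rois)
            for s in (*train_ids, *test_ids)
        }
        fm = features.build_feature_matrix(
            tuple(train_ids), tuple(test_ids), matrices, rois.roi_names
        )
        n_train = len(train_ids)
        X_train, X_test = fm.values[:n_train], fm.values[n_train:]
        y_train = np.array([prepared.labels[s] for s in train_ids])
        y_test = np.array([prepared.labels[s] for s in test_ids])

        clf_seed = derive_seed(plan.seed, f"clf:{contrast}:{classifier.family}:{f}")
        inner = StratifiedKFold(
            n_splits=plan.n_inner, shuffle=True, random_state=clf_seed
        )
        search = GridSearchCV(
            classifier.make_estimator(clf_seed),
            classifier.grid,
            scoring="roc_auc",
            cv=inner,
            n_jobs=1,
        )
        try:
            search.fit(X_train, y_train)
        except Exception:
            logger.exception("fold %d: classifier fit failed", f)
            folds.append(FoldResult(fold=f, skipped=True, test_ids=tuple(test_ids)))
            continue
        model = search.best_estimator_
        scores = _score(model, X_test)
        y_pred = model.predict(X_test)

        col_shap = None
        if compute_shap:
            try:
                col_shap = explain.shap_on_test(
                    model,
                    X_test,
                    X_train,
                    seed=derive_seed(plan.seed, f"shap:{contrast}:{classifier.family}:{f}"),
                )
            except Exception:
                logger.exception("fold %d: SHAP attribution failed", f)

        folds.append(
            FoldResult(
                fold=f,
                skipped=False,
                roi_names=rois.roi_names,
                k=rois.k,
                t_use=fm.t_use,
                test_ids=tuple(test_ids),
                y_true=y_test,
                y_pred=y_pred,
                scores=scores,
                best_params=dict(search.best_params_),
                column_shap=col_shap,
                metrics=compute_metrics(y_test, y_pred, scores)
                if len(np.unique(y_test)) == 2
                else None,
            )
        )
        pooled_true.append(y_test)
        pooled_pred.append(y_pred)
        pooled_scores.append(scores)

    skipped = sum(fr.skipped for fr in folds)
    if not pooled_true:
        raise RuntimeError(
            "every outer fold was skipped (no abnormal ROIs); nothing to evaluate"
        )
    y_true = np.concatenate(pooled_true)
    y_pred = np.concatenate(pooled_pred)
    scores = np.concatenate(pooled_scores)
    metrics = compute_metrics(y_true, y_pred, scores)
    boot = bootstrap_ci(
        y_true, y_pred, scores, n_boot=n_boot, seed=derive_seed(plan.seed, f"boot:{contrast}:{classifier.family}")
    )
    importance = None
    if compute_shap:
        fold_shap = [
            (fr.column_shap, fr.roi_names, fr.t_use)
            for fr in folds
            if not fr.skipped and fr.column_shap is not None
        ]
        if fold_shap:
            importance = explain.aggregate_to_rois(fold_shap)
    return EvaluationReport(
        contrast=contrast,
        classifier=classifier.family,
        metrics=metrics,
        folds=folds,
        bootstrap=boot,
        skipped_folds=skipped,
        importance=importance,
    )
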