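"""ROI-level importance from per-fold Shapley attribution on held-out data.

Within each outer fold, attributions are computed on the TEST subjects with
an explainer matched to the fitted model (exact linear explainer for linear
models, seeded permutation-sampling explainer otherwise), reduced to
per-column mean |attribution|, summed over each ROI's time-point columns,
and normalized to within-fold shares. Shares are then averaged across the
folds in which an ROI was selected (fold-varying ROI sets are the norm) and
renormalized to percentages, with the folds-present count reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC, SVC

from . import shapley

MAX_BACKGROUND = 25


@dataclass(frozen=True)
class ImportanceTable:
    """ROI importance ranking: share (%) of total attribution mass per ROI."""

    table: pd.DataFrame  # columns: roi, share, mean_abs_mass, folds_present

    def top(self, n: int) -> pd.DataFrame:
        return self.table.head(n)


def _is_linear(model) -> bool:
    if isinstance(model, (LogisticRegression, LinearSVC)):
        return True
    return isinstance(model, SVC) and model.kernel == "linear"


def _score_fn(model):
    if hasattr(model, "predict_proba"):
        return lambda X: model.predict_proba(X)[:, 1]
    return model.decision_function


def shap_values(
    model,
    X_test: np.ndarray,
    background: np.ndarray,
    seed: int = 0,
    n_permutations: int = 8,
) -> np.ndarray:
    """Per-sample, per-column Shapley attribution of the model's score.

    Linear models get the exact closed form on their decision function;
    everything else the permutation-sampling explainer on the class-1 score.
    The background is subsampled (seeded) to at most ``MAX_BACKGROUND`` rows.
    """
    background = np.asarray(background, dtype=float)
    if background.shape[0] > MAX_BACKGROUND:
        rng = np.random.default_rng(seed)
        background = background[
            rng.choice(background.shape[0], MAX_BACKGROUND, replace=False)
        ]
    if _is_linear(model):
        return shapley.linear_shap(model.coef_.ravel(), X_test, background)
    return shapley.permutation_shap(
        _score_fn(model), X_test, background, n_permutations=n_permutations, seed=seed
    )


def shap_on_test(
    model,
    X_test: np.ndarray,
    background: np.ndarray,
    seed: int = 0,
    n_permutations: int = 8,
) -> np.ndarray:
    """Per-column mean |Shapley value| over the held-out test subjects."""
    phi = shap_values(model, X_test, background, seed=seed, n_permutations=n_permutations)
    return np.abs(phi).mean(axis=0)


def aggregate_to_rois(
    fold_data: list[tuple[np.ndarray, tuple[str, ...], int]]
) -> ImportanceTable:
    """Merge per-fold column attributions into an ROI importance ranking.

    ``fold_data`` holds (per-column mean |attribution|, roi_names, t_use) per
    successful fold; columns are ROI-major, so ROI k owns columns
    [k * t_use, (k + 1) * t_use). Per fold, ROI masses are normalized to
    shares; shares are averaged over the folds where each ROI appears, then
    renormalized so the reported shares sum to 100%.
    """
    if not fold_data:
        raise ValueError("need at least one successful fold")
    share_sums: dict[str, float] = {}
    mass_sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for col_attr, roi_names, t_use in fold_data:
        col_attr = np.asarray(col_attr, dtype=float)
        k = len(roi_names)
        if col_attr.size != k * t_use:
            raise ValueError("column attribution length does not match K * T_use")
        masses = col_attr.reshape(k, t_use).sum(axis=1)
        total = masses.sum()
        shares = masses / total * 100.0 if total > 0 else np.zeros(k)
        for name, share, mass in zip(roi_names, shares, masses):
            share_sums[name] = share_sums.get(name, 0.0) + float(share)
            mass_sums[name] = mass_sums.get(name, 0.0) + float(mass)
            counts[name] = counts.get(name, 0) + 1
    rois = sorted(share_sums)
    mean_shares = np.array([share_sums[r] / counts[r] for r in rois])
    total = mean_shares.sum()
    if total > 0:
        mean_shares = mean_shares / total * 100.0
    table = pd.DataFrame(
        {
            "roi": rois,
            "share": mean_shares,
            "mean_abs_mass": [mass_sums[r] / counts[r] for r in rois],
            "folds_present": [counts[r] for r in rois],
        }
    ).sort_values("share", ascending=False, kind="mergesort", ignore_index=True)
    return ImportanceTable(table=table)
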