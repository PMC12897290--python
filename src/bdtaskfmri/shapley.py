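"""Shapley-value attribution of model scores to input features.

Two explainers, both interventional (feature removal = replacement by
background-sample values):

* exact linear explainer — for a linear score f(x) = w'x + b the Shapley
  value of feature j is w_j (x_j - mean(background_j)), exactly;
* permutation-sampling explainer — for arbitrary score functions, marginal
  contributions are accumulated along sampled feature permutations against a
  background set. Each permutation's contributions telescope from the
  background mean score to the sample's own score, so local accuracy
  (sum of attributions + base value = score) holds exactly for any number of
  sampled permutations.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def linear_shap(weights: np.ndarray, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values of a linear score w'x + b.

    Returns an (n_samples, n_features) attribution matrix.
    """
    weights = np.asarray(weights, dtype=float).reshape(-1)
    mu = np.asarray(background, dtype=float).mean(axis=0)
    return (np.asarray(X, dtype=float) - mu) * weights


def permutation_shap(
    score_fn: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Sampling-based Shapley values for an arbitrary score function.

    For each sample x and each sampled permutation pi of the features, the
    background rows are overwritten with x's features in pi order; the change
    in the mean score at each step is feature pi[i]'s marginal contribution.
    Attributions are averaged over ``n_permutations`` permutations.
    Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, d = X.shape
    nb = background.shape[0]
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, d))
    for i in range(n):
        x = X[i]
        for _ in range(n_permutations):
            order = rng.permutation(d)
            # stacked blocks: block 0 = pure background, block k = background
            # with the first k features (in pi order) replaced by x
            blocks = np.tile(background, (d + 1, 1)).reshape(d + 1, nb, d)
            for k, j in enumerate(order, start=1):
                blocks[k:, :, j] = x[j]
            preds = score_fn(blocks.reshape(-1, d)).reshape(d + 1, nb).mean(axis=1)
            phi[i, order] += np.diff(preds) / n_permutations
    return phi
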