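"""Shared small utilities: seed derivation and validation helpers."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(seed: int, tag: str) -> int:
    """Derive a stage-specific RNG seed from a master seed and a tag.

    One master seed governs the whole pipeline (cohort, folds, classifier
    randomness, bootstrap, Shapley sampling); stages draw from independent
    streams keyed by a human-readable tag so adding a stage never perturbs
    another stage's stream. Result is always in [0, 2**31).
    """
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def check_finite(arr, name: str) -> None:
    arr = np.asarray(arr)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
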