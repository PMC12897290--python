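"""Canonical double-gamma hemodynamic response function.

The HRF links a neural event (boxcar of condition 'on' time) to the delayed,
dispersed BOLD response. The canonical double-gamma has a positive lobe
peaking ~6 s after onset and a shallower undershoot peaking ~16 s, with a
peak-to-undershoot amplitude ratio of 6. Event regressors are built on a
micro-time grid (so sub-TR onsets are handled exactly up to the micro-grid
resolution) and then decimated to volume acquisition times.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

PEAK_DELAY_S = 6.0
UNDERSHOOT_DELAY_S = 16.0
DISPERSION_S = 1.0
UNDERSHOOT_DISPERSION_S = 1.0
PEAK_UNDERSHOOT_RATIO = 6.0
HRF_LENGTH_S = 32.0


def double_gamma(t: np.ndarray) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds).

    Normalized so the positive peak equals 1.
    """
    t = np.asarray(t, dtype=float)
    pos = stats.gamma.pdf(t, PEAK_DELAY_S / DISPERSION_S, scale=DISPERSION_S)
    neg = stats.gamma.pdf(
        t, UNDERSHOOT_DELAY_S / UNDERSHOOT_DISPERSION_S, scale=UNDERSHOOT_DISPERSION_S
    )
    h = pos - neg / PEAK_UNDERSHOOT_RATIO
    h[t < 0] = 0.0
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def convolve_events(
    onsets: np.ndarray,
    durations: np.ndarray,
    tr_s: float,
    n_volumes: int,
    dt_s: float = 0.1,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at volume times.

    Onsets and durations are in seconds and need not align to volume
    boundaries; the boxcar is rasterized on a ``dt_s`` micro-time grid,
    convolved with the HRF, and sampled at ``t = k * tr_s``.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(
        np.atleast_1d(np.asarray(durations, dtype=float)), onsets.shape
    )
    total_s = n_volumes * tr_s + HRF_LENGTH_S
    n_micro = int(np.ceil(total_s / dt_s)) + 1
    boxcar = np.zeros(n_micro)
    for onset, dur in zip(onsets, durations):
        i0 = int(np.round(onset / dt_s))
        i1 = max(i0 + 1, int(np.round((onset + dur) / dt_s)))
        boxcar[i0:i1] = 1.0
    kernel = double_gamma(np.arange(0, HRF_LENGTH_S + dt_s, dt_s))
    conv = np.convolve(boxcar, kernel)[:n_micro] * dt_s
    vol_idx = np.round(np.arange(n_volumes) * tr_s / dt_s).astype(int)
    return conv[vol_idx]
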