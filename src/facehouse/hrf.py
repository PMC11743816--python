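"""Canonical hemodynamic response and condition-regressor construction.

The same convolution machinery is used by the forward simulator and by the
first-level design matrix, so a noiseless simulation is exactly invertible
by the GLM.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: Fine-grid oversampling factor relative to the repetition time.
OVERSAMPLING = 20


def double_gamma_hrf(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
):
    """Canonical double-gamma impulse response (SPM parameterization).

    Difference of two gamma densities with shape ``delay / dispersion`` and
    scale ``dispersion``; the undershoot is scaled by ``undershoot_ratio``.
    """
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    under = stats.gamma.pdf(t, undershoot_delay / dispersion, scale=dispersion)
    return peak - undershoot_ratio * under


def sampled_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """HRF sampled every ``dt`` seconds, normalized to unit time-integral."""
    t = np.arange(0.0, duration + dt / 2, dt)
    h = double_gamma_hrf(t)
    return h / (h.sum() * dt)


def condition_regressor(spans, tr: float, n_frames: int) -> np.ndarray:
    """HRF-convolved boxcar for one condition, sampled at frame midpoints.

    ``spans`` is a sequence of (onset_s, duration_s) stimulus-sequence
    spans.  The boxcar is built on a fine grid (``tr / OVERSAMPLING``),
    convolved with the unit-integral HRF, and read out at times
    ``(i + 0.5) * tr``.  The time-integral of the regressor equals the total
    boxcar duration (up to end-of-scan truncation).
    """
    dt = tr / OVERSAMPLING
    n_fine = n_frames * OVERSAMPLING
    box = np.zeros(n_fine)
    for onset, dur in spans:
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        box[i0:i1] = 1.0
    conv = np.convolve(box, sampled_hrf(dt))[:n_fine] * dt
    mid = (np.arange(n_frames) * OVERSAMPLING) + OVERSAMPLING // 2
    return conv[mid]


def dct_highpass_basis(n_frames: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift regressors for periods longer than ``cutoff_s``.

    Returns the ``K = floor(2 * n_frames * tr / cutoff_s)`` lowest-order
    DCT-II basis functions (the constant term excluded), as columns.
    """
    n_basis = int(np.floor(2.0 * n_frames * tr / cutoff_s))
    i = np.arange(n_frames)
    cols = [
        np.sqrt(2.0 / n_frames) * np.cos(np.pi * k * (2 * i + 1) / (2 * n_frames))
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))
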