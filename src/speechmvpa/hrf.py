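"""Hemodynamic and respiratory response kernels.

The canonical double-gamma HRF (the SPM "SPMG1" shape) models the delayed
BOLD response to a neural event: a gamma-density peak around 5 s followed by
a shallow undershoot around 15 s.  Trials in a sparse-sampled slow
event-related speech design are modelled as a 6 s boxcar (three utterances
separated by one TR) convolved with this kernel.

A separate gamma kernel models the global respiratory response to the
inhalation that precedes each trial's articulation; its peak latency
(default 8 s) is the quantity the trial-locked gray-matter average
(resp-IRF) is expected to recover.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = [
    "double_gamma_hrf",
    "respiratory_kernel",
    "trial_response",
    "epoch_response",
]

#: dense-grid resolution (s) used for all convolutions before TR sampling
DENSE_DT = 0.05


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (s), peak 1.

    ``h(t) = g(t; a1) - g(t; a2)/c`` with unit-scale gamma densities;
    defaults give the familiar ~5 s peak and ~15 s undershoot.  The kernel
    is normalised so its maximum is 1, making planted amplitudes directly
    interpretable as peak signal change.
    """
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, peak_delay_s) - _gamma.pdf(t, undershoot_delay_s) / undershoot_ratio
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def respiratory_kernel(t: np.ndarray, peak_s: float = 8.0, shape: float = 5.0) -> np.ndarray:
    """Gamma kernel with mode ``peak_s`` modelling the respiratory response.

    Shape ``k`` and scale ``theta = peak_s / (k - 1)`` place the mode exactly
    at ``peak_s``; the maximum is normalised to 1.
    """
    if peak_s <= 0:
        raise ValueError("peak_s must be positive")
    t = np.asarray(t, dtype=float)
    scale = peak_s / (shape - 1.0)
    h = _gamma.pdf(t, shape, scale=scale)
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def _boxcar_conv(kernel_fn, duration_s: float, t_max_s: float, **kw) -> tuple[np.ndarray, np.ndarray]:
    """Convolve a unit boxcar of ``duration_s`` with a kernel on a dense grid."""
    tt = np.arange(0.0, t_max_s + DENSE_DT, DENSE_DT)
    k = kernel_fn(tt, **kw)
    box = (tt < duration_s).astype(float)
    resp = np.convolve(box, k)[: tt.size] * DENSE_DT
    m = np.abs(resp).max()
    if m > 0:
        resp = resp / m
    return tt, resp


def trial_response(
    duration_s: float = 6.0,
    tr_s: float = 2.0,
    n_vols: int = 9,
    kernel=double_gamma_hrf,
    **kernel_kw,
) -> np.ndarray:
    """Unit-amplitude response of one trial sampled on the TR grid.

    A boxcar of ``duration_s`` convolved with ``kernel`` on a dense grid,
    normalised to peak 1, sampled at lags ``0, tr_s, ..., (n_vols-1)*tr_s``.
    """
    t_max = (n_vols - 1) * tr_s
    tt, resp = _boxcar_conv(kernel, duration_s, t_max + tr_s, **kernel_kw)
    lags = np.arange(n_vols) * tr_s
    idx = np.round(lags / DENSE_DT).astype(int)
    return resp[idx]


def epoch_response(tr_s: float = 2.0, n_lags: int = 9, **kw) -> np.ndarray:
    """Alias of :func:`trial_response` for the 16 s / 9-sample epoch grid."""
    return trial_response(tr_s=tr_s, n_vols=n_lags, **kw)
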