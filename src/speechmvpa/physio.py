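"""Physiological summaries: condition trace comparison and the resp-IRF.

The trial-locked average fMRI signal over all cortical gray-matter voxels
serves as a proxy for the respiration-driven impulse response (resp-IRF);
in a well-behaved speech design it peaks around 8 s after the inhalation
at trial onset and does not differ between voiced and whispered speech.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import fdr_bh

__all__ = ["TraceComparison", "RespIRF", "compare_traces", "compute_resp_irf"]


@dataclass
class TraceComparison:
    t: np.ndarray
    p: np.ndarray
    sig_uncorrected: np.ndarray
    sig_fdr: np.ndarray
    alpha: float
    fdr_q: float


@dataclass
class RespIRF:
    timepoints_s: np.ndarray       # TR-spaced lags from trial onset
    mean_response: np.ndarray      # curve starts at 0 (lag-0 subtracted)
    per_trial: np.ndarray          # (n_trials, n_lags)

    @property
    def peak_lag_s(self) -> float:
        return float(self.timepoints_s[int(np.argmax(self.mean_response))])


def compare_traces(traces_a: np.ndarray, traces_b: np.ndarray,
                   alpha: float = 0.05, fdr_q: float = 0.05) -> TraceComparison:
    """Pointwise paired two-tailed t-tests between two condition traces.

    Inputs are (n_subjects, n_timepoints) trial-averaged traces, one row per
    subject, matched across conditions.  BH-FDR is applied over time points.
    """
    a = np.asarray(traces_a, dtype=float)
    b = np.asarray(traces_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition traces must have matching shape")
    if a.ndim != 2 or a.shape[0] < 3:
        raise ValueError("need (n_subjects >= 3, n_timepoints) traces")
    from scipy import stats as _st

    d = a - b
    sd = d.std(axis=0, ddof=1)
    t = np.zeros(a.shape[1])
    p = np.ones(a.shape[1])
    live = sd > 0
    if live.any():
        t[live], p[live] = _st.ttest_rel(a[:, live], b[:, live], axis=0)
    res = fdr_bh(p, fdr_q)
    return TraceComparison(t, p, p < alpha, res.rejected, alpha, fdr_q)


def compute_resp_irf(
    volumes: list[np.ndarray],
    gray_mask: np.ndarray,
    trial_table: pd.DataFrame,
    tr_s: float = 2.0,
    n_lags: int = 9,
) -> RespIRF:
    """Trial-onset-locked gray-matter average response on the TR grid.

    For each trial the ``n_lags``-sample epoch is extracted, averaged over
    gray-mask voxels, and averaged over trials; the lag-0 value is
    subtracted so curves start at 0.  Trials whose epoch exceeds the run are
    skipped.
    """
    gray_mask = np.asarray(gray_mask, dtype=bool)
    if not gray_mask.any():
        raise ValueError("gray mask is empty")
    epochs = []
    for run, grp in trial_table.groupby("run"):
        vol4d = volumes[int(run)]
        gm_ts = vol4d[gray_mask].mean(axis=0)       # (n_vols,)
        n_vols = gm_ts.size
        for onset in grp["onset_s"].to_numpy():
            start = int(round(onset / tr_s))
            if start + n_lags > n_vols:
                continue
            epochs.append(gm_ts[start : start + n_lags])
    if not epochs:
        raise ValueError("no complete trial epochs")
    per_trial = np.asarray(epochs, dtype=float)
    mean = per_trial.mean(axis=0)
    mean = mean - mean[0]
    return RespIRF(np.arange(n_lags) * tr_s, mean, per_trial)
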