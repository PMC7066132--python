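"""Shared statistical kernel: t-tests, label permutation, Benjamini-Hochberg.

Every decoding and mapping stage funnels its inference through these three
primitives so conventions (two-tailed tests, within-run permutation, step-up
FDR) are applied uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

__all__ = ["FDRResult", "fdr_bh", "paired_t", "one_sample_t", "permute_labels"]


@dataclass
class FDRResult:
    """Outcome of a Benjamini-Hochberg step-up correction."""

    p_values: np.ndarray
    q_threshold: float
    rejected: np.ndarray          # boolean, aligned with p_values
    largest_rejected_rank: int    # k* in the step-up rule, 0 if none
    crit_p: float = field(default=np.nan)  # p_(k*), NaN if none rejected

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def fdr_bh(p_values, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up FDR control at level ``q``.

    Rejects all hypotheses with ``p <= p_(k*)`` where
    ``k* = max{k : p_(k) <= k*q/m}`` over the sorted p-values.  Empty input
    yields an empty result.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return FDRResult(p, q, np.zeros(0, dtype=bool), 0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = (np.arange(1, m + 1) * q) / m
    passed = p[order] <= thresh
    if not passed.any():
        return FDRResult(p, q, np.zeros(m, dtype=bool), 0)
    k_star = int(np.nonzero(passed)[0][-1]) + 1
    crit = p[order][k_star - 1]
    rejected = p <= crit
    return FDRResult(p, q, rejected, k_star, crit)


def paired_t(a, b) -> tuple[float, float]:
    """Classical paired two-tailed t-test; returns ``(t, p)``.

    Zero variance of the differences is flagged with an infinite t (p=0)
    when the mean difference is nonzero, and (0, 1) when the samples are
    identical.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = _st.ttest_rel(a, b)
    return float(t), float(p)


def one_sample_t(x, popmean: float = 0.0, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed one-sample t along ``axis``; vectorised, NaN-safe for
    zero-variance columns (t = +/-inf, p = 0 when the mean differs)."""
    import warnings

    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = _st.ttest_1samp(x, popmean, axis=axis)
    mean = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    degenerate = np.isclose(sd, 0.0)
    if np.any(degenerate):
        null_mean = np.isclose(mean, popmean)
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate, np.where(null_mean, 0.0, np.sign(mean - popmean) * np.inf), t)
            p = np.where(degenerate, np.where(null_mean, 1.0, 0.0), p)
    return t, p


def permute_labels(labels, runs, rng) -> np.ndarray:
    """Uniform label shuffle *within each run*; class counts per run are
    preserved, which keeps leave-run-out folds valid under the null."""
    labels = np.asarray(labels)
    runs = np.asarray(runs)
    if labels.shape != runs.shape:
        raise ValueError("labels and runs must align")
    rng = np.random.default_rng(rng)
    out = labels.copy()
    for r in np.unique(runs):
        idx = np.nonzero(runs == r)[0]
        out[idx] = labels[idx[rng.permutation(idx.size)]]
    return out
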