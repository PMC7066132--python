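"""First-level GLM and single-trial feature estimation.

The subject-level model regresses each voxel's time series on
HRF-convolved condition regressors (10 task x item condition types, each
trial a 6 s boxcar), per-run Legendre drift polynomials (order 0..5), six
realignment parameters, and one indicator column per motion-censored
volume.  Single-trial features are then computed from the *nuisance-only*
residuals: 16 s epochs (9 TR-grid samples) locked to trial onset are
demeaned, detrended for a linear slope, and summarised to one scalar per
trial and voxel — the mean over the HRF peak window (lags 4-10 s).  The
trials x voxels matrix of these scalars (the "beta series") is the common
currency of all decoding and connectivity stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrf import DENSE_DT, double_gamma_hrf
from .stats import one_sample_t

__all__ = [
    "TASKS",
    "ITEMS",
    "CONDITIONS",
    "DesignMatrix",
    "BetaSeriesMatrix",
    "censor_frames",
    "build_design",
    "fit_glm",
    "extract_trial_features",
    "group_contrast",
    "epoch_summary_vector",
]

TASKS = ("voiced", "whispered")
ITEMS = ("bb", "dd", "mm", "nn", "schwa")
#: the 10 task x item condition types, in canonical order
CONDITIONS = tuple(f"{t}_{i}" for t in TASKS for i in ITEMS)

#: motion-censoring threshold on the Euclidean norm of the parameter
#: derivatives, in mm; strictly greater-than flags the volume
CENSOR_MM = 0.4

#: epoch grid: 9 samples spanning 16 s inclusive at TR 2 s
EPOCH_N_LAGS = 9
#: TR-lag indices averaged into the per-trial scalar (4-10 s, HRF peak)
PEAK_LAGS = (2, 5)


def _validate_trial_table(tt: pd.DataFrame) -> pd.DataFrame:
    required = {"onset_s", "run", "task", "item"}
    missing = required - set(tt.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    for r, grp in tt.groupby("run"):
        on = grp["onset_s"].to_numpy()
        if np.any(np.diff(on) <= 0):
            raise ValueError(f"onsets must be strictly increasing within run {r}")
    bad = set(tt["task"]) - set(TASKS)
    if bad:
        raise ValueError(f"unknown tasks: {sorted(bad)}")
    bad = set(tt["item"]) - set(ITEMS)
    if bad:
        raise ValueError(f"unknown items: {sorted(bad)}")
    return tt


def censor_frames(motion: np.ndarray, threshold_mm: float = CENSOR_MM) -> np.ndarray:
    """Flag volumes whose motion-derivative Euclidean norm exceeds the
    threshold (strict ``>``); the first volume is never flagged."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters contain non-finite values")
    d = np.diff(motion, axis=0)
    enorm = np.linalg.norm(d, axis=1)
    flags = np.zeros(motion.shape[0], dtype=bool)
    flags[1:] = enorm > threshold_mm
    return flags


def _legendre_block(n_vols: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n_vols)
    return np.column_stack([np.polynomial.legendre.Legendre.basis(k)(x) for k in range(order + 1)])


@dataclass
class DesignMatrix:
    """GLM design with named columns and index bookkeeping."""

    X: np.ndarray
    names: list[str]
    interest_idx: np.ndarray      # columns of the 10 condition regressors
    run_slices: dict[int, slice]  # volume rows belonging to each run
    censored: np.ndarray          # boolean per volume
    tr_s: float

    @property
    def n_vols(self) -> int:
        return self.X.shape[0]


def build_design(
    trial_table: pd.DataFrame,
    motion: np.ndarray | None,
    n_vols_per_run: dict[int, int] | int,
    tr_s: float = 2.0,
    drift_order: int = 5,
    trial_duration_s: float = 6.0,
    hrf=double_gamma_hrf,
) -> DesignMatrix:
    """Assemble the first-level design matrix on the concatenated TR grid.

    Condition regressors are 6 s boxcars (3 utterances separated by one TR)
    convolved with the double-gamma HRF on a dense grid and sampled at TR
    resolution, zero outside their own condition's trials.  Nuisance columns:
    Legendre polynomials 0..``drift_order`` per run, the 6 realignment
    parameters, and one indicator per censored volume.

    ``motion`` is mandatory: omitting it raises rather than silently
    dropping the nuisance block.
    """
    tt = _validate_trial_table(trial_table)
    runs = sorted(tt["run"].unique())
    if isinstance(n_vols_per_run, int):
        n_vols_per_run = {r: n_vols_per_run for r in runs}
    if motion is None:
        raise ValueError("motion table is required (no silent omission)")
    motion = np.asarray(motion, dtype=float)
    n_total = sum(n_vols_per_run[r] for r in runs)
    if motion.shape != (n_total, 6):
        raise ValueError(f"motion table must be {(n_total, 6)}, got {motion.shape}")

    run_slices: dict[int, slice] = {}
    start = 0
    for r in runs:
        run_slices[r] = slice(start, start + n_vols_per_run[r])
        start += n_vols_per_run[r]

    # condition regressors via dense-grid convolution per run
    interest = np.zeros((n_total, len(CONDITIONS)))
    for r in runs:
        sl = run_slices[r]
        n_vols = n_vols_per_run[r]
        dur = n_vols * tr_s
        tt_r = tt[tt["run"] == r]
        if np.any(tt_r["onset_s"].to_numpy() + trial_duration_s > dur):
            raise ValueError(f"trial onset beyond end of run {r}")
        dense_n = int(round(dur / DENSE_DT))
        dense_t = np.arange(dense_n) * DENSE_DT
        kern = hrf(np.arange(0.0, 32.0, DENSE_DT))
        for ci, cond in enumerate(CONDITIONS):
            task, item = cond.split("_")
            onsets = tt_r.loc[(tt_r["task"] == task) & (tt_r["item"] == item), "onset_s"].to_numpy()
            if onsets.size == 0:
                continue
            box = np.zeros(dense_n)
            for o in onsets:
                box[(dense_t >= o) & (dense_t < o + trial_duration_s)] = 1.0
            reg = np.convolve(box, kern)[:dense_n] * DENSE_DT
            samp = reg[np.round(np.arange(n_vols) * tr_s / DENSE_DT).astype(int)]
            interest[sl, ci] = samp
    # common scale: unit peak for a single isolated trial
    peak = np.abs(interest).max()
    if peak > 0:
        interest /= peak

    blocks = [interest]
    names = list(CONDITIONS)

    for r in runs:
        leg = _legendre_block(n_vols_per_run[r], drift_order)
        block = np.zeros((n_total, drift_order + 1))
        block[run_slices[r]] = leg
        blocks.append(block)
        names += [f"legendre{k}_run{r}" for k in range(drift_order + 1)]

    blocks.append(motion)
    names += [f"motion{k}" for k in range(6)]

    censored = censor_frames(motion)
    cens_idx = np.nonzero(censored)[0]
    if cens_idx.size:
        ind = np.zeros((n_total, cens_idx.size))
        ind[cens_idx, np.arange(cens_idx.size)] = 1.0
        blocks.append(ind)
        names += [f"censor_vol{int(v)}" for v in cens_idx]

    X = np.column_stack(blocks)
    interest_idx = np.arange(len(CONDITIONS))
    return DesignMatrix(X, names, interest_idx, run_slices, censored, tr_s)


def fit_glm(data: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least squares per voxel.

    ``data`` is (n_vols, n_voxels).  Returns ``(betas, residuals)`` where
    ``betas`` is (n_regressors, n_voxels) and residuals are the data minus
    every fitted column.  Raises on rank deficiency, naming the collinear
    columns.
    """
    data = np.asarray(data, dtype=float)
    X = design.X
    if data.shape[0] != X.shape[0]:
        raise ValueError("data rows must equal design rows")
    # rank check via QR: near-zero diagonal entries localise collinearity
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = np.nonzero(diag < tol)[0]
    if bad.size:
        cols = ", ".join(design.names[i] for i in bad)
        raise ValueError(f"design matrix is rank deficient (collinear columns: {cols})")
    betas, *_ = np.linalg.lstsq(X, data, rcond=None)
    residuals = data - X @ betas
    return betas, residuals


def nuisance_residuals(data: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Residuals after regressing out only the nuisance columns (drift,
    motion, censor indicators), leaving condition responses in the data —
    the input expected by :func:`extract_trial_features`."""
    data = np.asarray(data, dtype=float)
    keep = np.setdiff1d(np.arange(design.X.shape[1]), design.interest_idx)
    Xn = design.X[:, keep]
    betas, *_ = np.linalg.lstsq(Xn, data, rcond=None)
    return data - Xn @ betas


def epoch_summary_vector(n_lags: int = EPOCH_N_LAGS, peak_lags: tuple[int, int] = PEAK_LAGS) -> np.ndarray:
    """Linear functional c such that the per-trial scalar equals c . epoch.

    Encodes demeaning, linear detrending and the peak-window mean, so both
    the extractor and the synthetic generator agree exactly on how a raw
    epoch maps to a feature (the generator uses ||c|| to calibrate planted
    effect sizes).
    """
    t = np.arange(n_lags, dtype=float)
    A = np.column_stack([np.ones(n_lags), t])
    P = np.eye(n_lags) - A @ np.linalg.pinv(A)
    m = np.zeros(n_lags)
    lo, hi = peak_lags
    m[lo : hi + 1] = 1.0 / (hi - lo + 1)
    return P.T @ m


@dataclass
class BetaSeriesMatrix:
    """Trials x voxels single-trial response amplitudes."""

    values: np.ndarray            # (n_kept_trials, n_voxels)
    trial_table: pd.DataFrame     # the kept trials, original index preserved
    voxel_index: np.ndarray       # (n_voxels, 3) array coordinates, or column ids
    dropped_trials: list[int] = field(default_factory=list)
    epochs: np.ndarray | None = None  # (n_kept, n_lags, n_voxels) if retained

    @property
    def labels_task(self) -> np.ndarray:
        return self.trial_table["task"].to_numpy()

    @property
    def runs(self) -> np.ndarray:
        return self.trial_table["run"].to_numpy()


def extract_trial_features(
    residuals: np.ndarray,
    trial_table: pd.DataFrame,
    design: DesignMatrix,
    voxel_index: np.ndarray | None = None,
    n_lags: int = EPOCH_N_LAGS,
    peak_lags: tuple[int, int] = PEAK_LAGS,
    max_censored_frac: float = 1.0 / 3.0,
    keep_epochs: bool = False,
) -> BetaSeriesMatrix:
    """Epoch-based single-trial feature estimation.

    For each trial, the 9-sample TR-grid epoch locked to trial onset is
    demeaned, detrended for a linear slope, and summarised as the mean over
    TR lags ``peak_lags`` (inclusive; default lags 2-5 = 4-10 s).  Trials
    whose epoch would run past the end of the run, or whose epoch contains
    more than ``max_censored_frac`` censored volumes, are dropped and
    reported in ``dropped_trials``.
    """
    tt = _validate_trial_table(trial_table)
    residuals = np.asarray(residuals, dtype=float)
    tr = design.tr_s
    c = epoch_summary_vector(n_lags, peak_lags)

    rows, kept_idx, dropped, epochs = [], [], [], []
    for idx, trial in tt.iterrows():
        sl = design.run_slices[trial["run"]]
        start_lag = trial["onset_s"] / tr
        start = sl.start + int(round(start_lag))
        if not np.isclose(start_lag, round(start_lag)):
            raise ValueError("trial onsets must lie on the TR grid")
        stop = start + n_lags
        if stop > sl.stop:
            dropped.append(idx)
            continue
        if design.censored[start:stop].sum() > max_censored_frac * n_lags:
            dropped.append(idx)
            continue
        epoch = residuals[start:stop]
        rows.append(c @ epoch)
        kept_idx.append(idx)
        if keep_epochs:
            t = np.arange(n_lags, dtype=float)
            A = np.column_stack([np.ones(n_lags), t])
            epochs.append(epoch - A @ np.linalg.lstsq(A, epoch, rcond=None)[0])
    if not rows:
        raise ValueError("no trials survived epoch extraction")
    if dropped:
        import warnings

        warnings.warn(
            f"dropped {len(dropped)} trial(s) (epoch past run end or censor-dominated): "
            f"{dropped}", stacklevel=2,
        )
    values = np.vstack(rows)
    if voxel_index is None:
        voxel_index = np.arange(residuals.shape[1])
    return BetaSeriesMatrix(
        values=values,
        trial_table=tt.loc[kept_idx].copy(),
        voxel_index=np.asarray(voxel_index),
        dropped_trials=dropped,
        epochs=np.stack(epochs) if keep_epochs and epochs else None,
    )


def group_contrast(subject_betas: np.ndarray, contrast: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group-level t-map for a condition contrast.

    ``subject_betas`` is (n_subjects, n_conditions, n_voxels); ``contrast``
    a length-``n_conditions`` vector that must sum to zero.  Per voxel,
    a two-tailed one-sample t across subjects on the contrast values
    (equivalent to a paired t on condition differences).  P-values are
    uncorrected by convention at this stage.
    """
    subject_betas = np.asarray(subject_betas, dtype=float)
    contrast = np.asarray(contrast, dtype=float)
    if subject_betas.ndim != 3:
        raise ValueError("subject_betas must be (n_subjects, n_conditions, n_voxels)")
    if subject_betas.shape[0] < 3:
        raise ValueError("group contrast needs >= 3 subjects")
    if contrast.shape != (subject_betas.shape[1],):
        raise ValueError("contrast length must equal number of conditions")
    if not np.isclose(contrast.sum(), 0.0):
        raise ValueError("contrast vector must sum to zero")
    values = np.einsum("c,scv->sv", contrast, subject_betas)
    return one_sample_t(values, 0.0, axis=0)


def contrast_vector(kind: str) -> np.ndarray:
    """Named condition contrasts over the 10 canonical condition types."""
    c = np.zeros(len(CONDITIONS))
    for i, cond in enumerate(CONDITIONS):
        task, item = cond.split("_")
        if kind == "voiced-vs-whispered":
            c[i] = 1.0 if task == "voiced" else -1.0
        elif kind == "bilabial-vs-alveolar":
            c[i] = {"bb": 1.0, "mm": 1.0, "dd": -1.0, "nn": -1.0}.get(item, 0.0)
        elif kind == "oral-vs-nasal":
            c[i] = {"bb": 1.0, "dd": 1.0, "mm": -1.0, "nn": -1.0}.get(item, 0.0)
        else:
            raise ValueError(f"unknown contrast {kind!r}")
    return c / np.abs(c).sum() * 2.0
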