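"""Seed-based beta-series functional connectivity.

The beta series — one response amplitude per trial and voxel — captures
trial-to-trial co-fluctuation while ignoring within-trial temporal
structure, which a 2 s TR cannot resolve anyway.  A seed region (here a
subject-level functional cluster, e.g. lip or tongue motor cortex) is
summarised by its mean beta series; Pearson correlation against every
voxel, Fisher z-transformed, yields a connectivity map per subject.
Group maps are one-sample t-tests of z against zero; condition-specific
connectivity is assessed by paired contrasts of z maps computed on
condition subsets of trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi
from scipy import stats as _st

from .stats import one_sample_t

__all__ = [
    "SeedRegion",
    "ConnectivityMap",
    "localize_seed",
    "seed_correlation",
    "group_connectivity",
    "contrast_connectivity",
    "fisher_z",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_R_GUARD = 1.0 - 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher's r-to-z, with |r| clipped just inside 1 before atanh."""
    return np.arctanh(np.clip(r, -_R_GUARD, _R_GUARD))


@dataclass
class SeedRegion:
    name: str
    voxels: np.ndarray             # (n, 3) coordinates
    threshold_p: float
    peak_coord: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]


def localize_seed(subject_t_map: np.ndarray, df: int, anatomical_mask: np.ndarray,
                  threshold_p: float = 0.05, name: str = "seed") -> SeedRegion | None:
    """Largest suprathreshold cluster of a subject contrast inside a mask.

    The t-map is thresholded at uncorrected two-tailed ``p < threshold_p``
    with positive sign (the localising direction of the contrast), masked
    anatomically, and split into 26-connected clusters; the largest is the
    seed.  Returns ``None`` (subject flagged) if nothing survives.
    """
    t = np.asarray(subject_t_map, dtype=float)
    mask = np.asarray(anatomical_mask, dtype=bool)
    if t.shape != mask.shape:
        raise ValueError("t-map and mask must share a grid")
    p = 2 * _st.t.sf(np.abs(t), df)
    supra = (p < threshold_p) & (t > 0) & mask
    if not supra.any():
        return None
    lab, n = _ndi.label(supra, structure=_CONN26)
    sizes = _ndi.sum_labels(supra, lab, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    voxels = np.argwhere(lab == best)
    peak_idx = np.argmax(t[lab == best])
    peak = tuple(int(v) for v in voxels[peak_idx])
    return SeedRegion(name, voxels, threshold_p, peak)


@dataclass
class ConnectivityMap:
    r: np.ndarray                  # per voxel (flat over analysis columns)
    z: np.ndarray
    seed_name: str
    n_trials: int
    missing: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def seed_correlation(beta_matrix: np.ndarray, seed_columns: np.ndarray,
                     trial_subset: np.ndarray | None = None,
                     seed_name: str = "seed", min_trials: int = 10) -> ConnectivityMap:
    """Correlate the mean seed beta series with every voxel's series.

    ``beta_matrix`` is (trials, voxels); ``seed_columns`` indexes the seed
    voxels; ``trial_subset`` restricts to a condition's trials.  Voxels
    with zero variance get NaN r, recorded in ``missing``.
    """
    B = np.asarray(beta_matrix, dtype=float)
    if trial_subset is not None:
        B = B[np.asarray(trial_subset)]
    if B.shape[0] < min_trials:
        raise ValueError(f"need >= {min_trials} trials in the subset")
    seed_ts = B[:, np.asarray(seed_columns)].mean(axis=1)
    Bc = B - B.mean(axis=0)
    sc = seed_ts - seed_ts.mean()
    denom = np.sqrt((Bc**2).sum(axis=0)) * np.sqrt((sc**2).sum())
    missing = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Bc.T @ sc) / denom
    r[missing] = np.nan
    z = np.where(missing, np.nan, fisher_z(np.where(missing, 0.0, r)))
    return ConnectivityMap(r, z, seed_name, B.shape[0], missing)


def group_connectivity(z_maps: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel two-sided one-sample t of subject z maps against zero."""
    Z = np.stack([np.asarray(z, dtype=float) for z in z_maps])
    if Z.shape[0] < 3:
        raise ValueError("group connectivity needs >= 3 subjects")
    return one_sample_t(Z, 0.0, axis=0)


def contrast_connectivity(z_maps_a: list[np.ndarray],
                          z_maps_b: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-voxel t of condition-A minus condition-B z maps
    (same subjects, same order, in both lists)."""
    if len(z_maps_a) != len(z_maps_b):
        raise ValueError("condition lists must contain the same subjects")
    A = np.stack([np.asarray(z, dtype=float) for z in z_maps_a])
    B = np.stack([np.asarray(z, dtype=float) for z in z_maps_b])
    if A.shape != B.shape:
        raise ValueError("condition z maps must share a grid")
    return one_sample_t(A - B, 0.0, axis=0)
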