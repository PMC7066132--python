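"""Volumetric searchlight decoding with cluster-contiguity voxel selection.

A 7 mm sphere (123 voxels at 2 mm isotropic) is centred on every
gray-matter voxel.  Because a volumetric sphere can straddle folds of
cortex that are far apart along the sheet, the masked sphere is split into
26-connected components and only the component containing the centroid is
kept.  Each sphere is decoded with a shrinkage-regularised linear
discriminant under leave-run-out cross-validation; within-run label
permutations give per-voxel p-values and BH-FDR controls the map-wise
false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi
from sklearn.base import BaseEstimator

from .stats import fdr_bh, one_sample_t, permute_labels

__all__ = [
    "SphereSpec",
    "SearchlightMap",
    "build_sphere",
    "contiguity_filter",
    "lda_accuracy",
    "SearchlightDecoder",
    "run_searchlight",
    "group_searchlight",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SphereSpec:
    radius_mm: float
    voxel_mm: float
    offsets: np.ndarray    # (n, 3) integer offsets, includes (0,0,0)


def build_sphere(radius_mm: float = 7.0, voxel_mm: float = 2.0) -> SphereSpec:
    """Integer voxel offsets of the searchlight sphere.

    A 7 mm radius at 2 mm voxels reaches "3 voxels in every direction plus
    the centroid": membership uses the Euclidean norm in voxel units with
    an inclusive bound of ``floor(radius_mm / voxel_mm)`` voxels, giving
    123 offsets at the default settings.
    """
    if radius_mm < voxel_mm:
        raise ValueError("radius must be at least one voxel")
    m = int(np.floor(radius_mm / voxel_mm))
    grid = np.mgrid[-m : m + 1, -m : m + 1, -m : m + 1].reshape(3, -1).T
    keep = np.linalg.norm(grid, axis=1) <= m
    return SphereSpec(radius_mm, voxel_mm, grid[keep])


def contiguity_filter(sphere_mask: np.ndarray, centroid: tuple[int, int, int]) -> np.ndarray:
    """Keep only the 26-connected component containing the centroid.

    ``sphere_mask`` is a boolean array (the sphere intersected with the
    gray mask, in any local frame); ``centroid`` indexes into it and must
    be inside the mask.
    """
    sphere_mask = np.asarray(sphere_mask, dtype=bool)
    if not sphere_mask[centroid]:
        raise ValueError("centroid is outside the mask")
    lab, _ = _ndi.label(sphere_mask, structure=_CONN26)
    return lab == lab[centroid]


def _ledoit_wolf_cov(Xc: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrunk covariance of already-centered data.

    ``(1 - s) * S_emp + s * mu * I`` with the closed-form optimal shrinkage
    intensity; matches the standard estimator used for discriminant
    regularisation (biased empirical covariance, shrinkage toward the
    scaled identity).
    """
    n, p = Xc.shape
    emp = Xc.T @ Xc / n
    mu = np.trace(emp) / p
    X2 = Xc**2
    beta_ = np.sum(X2.T @ X2)
    delta_ = np.sum((Xc.T @ Xc) ** 2) / n**2
    beta_ = (beta_ / n - delta_) / (p * n)
    delta = (delta_ - 2.0 * mu * np.trace(emp) + p * mu**2) / p
    beta = min(beta_, delta)
    shrink = 0.0 if beta == 0 else beta / delta
    out = (1.0 - shrink) * emp
    out.flat[:: p + 1] += shrink * mu
    return out


def _lda_fit_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray) -> np.ndarray:
    """Shrinkage linear discriminant: fit on (Xtr, ytr), predict Xte.

    Pooled covariance = prior-weighted sum of per-class Ledoit-Wolf
    estimates (computed on standardised features and rescaled, so the
    shrinkage target treats all voxels alike); discriminant directions
    from a direct solve of the shrunk (positive definite) system.  The
    shrinkage keeps the problem well-posed when a sphere holds more
    voxels than training trials.  Computed inline because this sits in
    the searchlight's inner loop (one fit per sphere and fold).
    """
    classes = np.unique(ytr)
    n = ytr.size
    means, covs, priors = [], [], []
    for c in classes:
        Xc = Xtr[ytr == c]
        mu = Xc.mean(axis=0)
        means.append(mu)
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        lw = _ledoit_wolf_cov((Xc - mu) / sd)
        covs.append(sd[:, None] * lw * sd[None, :])
        priors.append(Xc.shape[0] / n)
    means = np.vstack(means)
    S = sum(p * C for p, C in zip(priors, covs))
    try:
        coef = np.linalg.solve(S, means.T).T
    except np.linalg.LinAlgError:  # zero-variance degenerate sphere
        coef = np.linalg.lstsq(S, means.T, rcond=None)[0].T
    intercept = -0.5 * np.einsum("ij,ij->i", means, coef) + np.log(priors)
    scores = Xte @ coef.T + intercept
    return classes[np.argmax(scores, axis=1)]


def lda_accuracy(features: np.ndarray, labels: np.ndarray,
                 folds: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Mean held-out accuracy of the shrinkage LDA over the given folds."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    accs = []
    for train, test in folds:
        pred = _lda_fit_predict(X[train], y[train], X[test])
        accs.append(float(np.mean(pred == y[test])))
    return float(np.mean(accs))


@dataclass
class SearchlightMap:
    accuracy: np.ndarray       # 3D, NaN outside computed voxels
    p: np.ndarray              # 3D permutation p, NaN outside
    q_significant: np.ndarray  # 3D boolean
    n_voxels_used: np.ndarray  # 3D int
    skipped: list[tuple[int, int, int]] = field(default_factory=list)


class SearchlightDecoder(BaseEstimator):
    """Whole-mask searchlight mapper (scikit-learn estimator style).

    ``fit(X, y, runs=..., mask=...)`` expects ``X`` as (trials, n_mask_voxels)
    beta-series features ordered like ``np.argwhere(mask)`` and produces
    ``map_`` with accuracy / permutation-p / FDR maps.
    """

    def __init__(self, radius_mm: float = 7.0, voxel_mm: float = 2.0,
                 n_permutations: int = 100, q: float = 0.05, rng_seed: int = 0,
                 min_sphere_voxels: int = 2):
        self.radius_mm = radius_mm
        self.voxel_mm = voxel_mm
        self.n_permutations = n_permutations
        self.q = q
        self.rng_seed = rng_seed
        self.min_sphere_voxels = min_sphere_voxels

    def fit(self, X, y, runs=None, mask=None):
        from .rfe import leave_run_out_folds

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if runs is None or mask is None:
            raise ValueError("runs and mask are required")
        mask = np.asarray(mask, dtype=bool)
        coords = np.argwhere(mask)
        if coords.shape[0] != X.shape[1]:
            raise ValueError("X columns must match mask voxels (argwhere order)")
        col_of = -np.ones(mask.shape, dtype=int)
        col_of[tuple(coords.T)] = np.arange(coords.shape[0])
        sphere = build_sphere(self.radius_mm, self.voxel_mm)
        folds = leave_run_out_folds(runs, y)
        rng = np.random.default_rng(self.rng_seed)
        perms = [permute_labels(y, runs, rng) for _ in range(self.n_permutations)]

        shape = mask.shape
        acc = np.full(shape, np.nan)
        pmap = np.full(shape, np.nan)
        nvox = np.zeros(shape, dtype=int)
        skipped: list[tuple[int, int, int]] = []

        for cx, cy, cz in coords:
            pts = sphere.offsets + (cx, cy, cz)
            ok = np.all((pts >= 0) & (pts < shape), axis=1)
            pts = pts[ok]
            inmask = mask[tuple(pts.T)]
            pts = pts[inmask]
            # contiguity: label the masked sphere in its local bounding box
            lo = pts.min(axis=0)
            local = np.zeros(pts.max(axis=0) - lo + 1, dtype=bool)
            local[tuple((pts - lo).T)] = True
            keep_local = contiguity_filter(local, tuple((cx, cy, cz) - lo))
            pts = pts[keep_local[tuple((pts - lo).T)]]
            if pts.shape[0] < self.min_sphere_voxels:
                skipped.append((int(cx), int(cy), int(cz)))
                continue
            cols = col_of[tuple(pts.T)]
            Xs = X[:, cols]
            a = lda_accuracy(Xs, y, folds)
            acc[cx, cy, cz] = a
            nvox[cx, cy, cz] = pts.shape[0]
            if self.n_permutations:
                null = np.asarray([lda_accuracy(Xs, yp, folds) for yp in perms])
                pmap[cx, cy, cz] = (1 + np.sum(null >= a)) / (1 + null.size)

        qsig = np.zeros(shape, dtype=bool)
        computed = ~np.isnan(pmap)
        if computed.any() and self.n_permutations:
            res = fdr_bh(pmap[computed], self.q)
            qsig[computed] = res.rejected
        self.map_ = SearchlightMap(acc, pmap, qsig, nvox, skipped)
        return self


def run_searchlight(beta_matrix, gray_mask, labels, runs,
                    radius_mm: float = 7.0, voxel_mm: float = 2.0,
                    n_permutations: int = 100, q: float = 0.05,
                    rng_seed: int = 0) -> SearchlightMap:
    """Functional wrapper over :class:`SearchlightDecoder`."""
    dec = SearchlightDecoder(radius_mm, voxel_mm, n_permutations, q, rng_seed)
    dec.fit(beta_matrix, labels, runs=runs, mask=gray_mask)
    return dec.map_


def group_searchlight(accuracy_maps: list[np.ndarray], chance: float | np.ndarray = 0.5,
                      q: float = 0.05) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel t of subject accuracies against chance, with BH-FDR.

    Returns ``(t_map, p_map, q_significant)``; voxels lacking a computed
    accuracy in any subject are NaN.
    """
    stack = np.stack([np.asarray(m, dtype=float) for m in accuracy_maps])
    valid = ~np.isnan(stack).any(axis=0)
    t_map = np.full(stack.shape[1:], np.nan)
    p_map = np.full(stack.shape[1:], np.nan)
    qsig = np.zeros(stack.shape[1:], dtype=bool)
    if valid.any():
        vals = stack[:, valid]
        ch = chance if np.isscalar(chance) else np.asarray(chance)[valid]
        t, p = one_sample_t(vals - ch, 0.0, axis=0)
        t_map[valid] = t
        p_map[valid] = p
        qsig[valid] = fdr_bh(p, q).rejected
    return t_map, p_map, qsig
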