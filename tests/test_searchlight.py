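"""Searchlight decoding: sphere geometry, contiguity filtering, LDA."""

import numpy as np
import pytest

from speechmvpa.rfe import leave_run_out_folds
from speechmvpa.searchlight import (
    SearchlightDecoder,
    build_sphere,
    contiguity_filter,
    lda_accuracy,
    run_searchlight,
)


class TestSphere:
    def test_unit_radius_gives_face_cross(self):
        assert build_sphere(2.0, 2.0).offsets.shape[0] == 7

    def test_default_sphere_matches_lattice_enumeration(self):
        """Brute-force oracle: count offsets in [-3,3]^3 within 3 voxels."""
        count = 0
        for i in range(-3, 4):
            for j in range(-3, 4):
                for k in range(-3, 4):
                    if i * i + j * j + k * k <= 9:
                        count += 1
        sphere = build_sphere(7.0, 2.0)
        assert sphere.offsets.shape[0] == count == 123
        assert np.abs(sphere.offsets).max() == 3

    def test_contains_origin_and_sign_symmetric(self):
        off = build_sphere(7.0, 2.0).offsets
        s = {tuple(o) for o in off}
        assert (0, 0, 0) in s
        assert all(tuple(-np.asarray(o)) in s for o in off)

    def test_radius_below_voxel_rejected(self):
        with pytest.raises(ValueError, match="at least one voxel"):
            build_sphere(1.0, 2.0)


class TestContiguity:
    def test_fully_connected_sphere_unchanged(self):
        m = np.ones((3, 3, 3), bool)
        assert contiguity_filter(m, (1, 1, 1)).sum() == 27

    def test_disconnected_slab_removed(self):
        m = np.zeros((5, 5, 5), bool)
        m[0] = True   # slab A
        m[4] = True   # slab B, separated by a 3-voxel gap
        kept = contiguity_filter(m, (0, 2, 2))
        assert kept[0].all() and not kept[4].any()

    def test_diagonal_touch_is_one_component_under_26_connectivity(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = m[1, 1, 1] = True
        kept = contiguity_filter(m, (0, 0, 0))
        assert kept[1, 1, 1]

    def test_centroid_outside_mask_rejected(self):
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            contiguity_filter(m, (2, 2, 2))


class TestLDA:
    def _folds(self, n, n_runs=2):
        runs = np.repeat(np.arange(n_runs), n // n_runs)
        y = np.asarray(["a", "b"] * (n // 2))
        return y, runs, leave_run_out_folds(runs, y)

    def test_separated_classes_reach_high_accuracy(self):
        rng = np.random.default_rng(0)
        y, runs, folds = self._folds(60)
        X = rng.standard_normal((60, 5))
        X[y == "a"] += 5.0
        assert lda_accuracy(X, y, folds) > 0.95

    def test_null_features_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(20):
            y, runs, folds = self._folds(60)
            accs.append(lda_accuracy(rng.standard_normal((60, 8)), y, folds))
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_univariate_problem_equals_midpoint_threshold_rule(self):
        """Closed form: one feature, equal priors -> nearest-class-mean rule."""
        rng = np.random.default_rng(2)
        y, runs, folds = self._folds(40)
        X = rng.standard_normal((40, 1)) + np.where(y == "a", 0.0, 1.0)[:, None]
        acc = lda_accuracy(X, y, folds)
        ref = []
        for train, test in folds:
            ma = X[train][y[train] == "a"].mean()
            mb = X[train][y[train] == "b"].mean()
            mid = 0.5 * (ma + mb)
            pred = np.where((X[test, 0] > mid) == (mb > ma), "b", "a")
            ref.append(np.mean(pred == y[test]))
        assert np.isclose(acc, np.mean(ref))

    def test_matches_sklearn_shrinkage_lda(self):
        """Independent oracle: per-fold predictions equal scikit-learn's
        lsqr/auto-shrinkage discriminant on random problems."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        from speechmvpa.searchlight import _lda_fit_predict

        rng = np.random.default_rng(9)
        for n, p in [(30, 5), (24, 40), (40, 12)]:
            X = rng.standard_normal((n, p))
            y = rng.choice(["a", "b"], n)
            while np.unique(y).size < 2 or min((y == "a").sum(), (y == "b").sum()) < 2:
                y = rng.choice(["a", "b"], n)
            tr, te = np.arange(n // 2), np.arange(n // 2, n)
            ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            ref.fit(X[tr], y[tr])
            assert np.array_equal(_lda_fit_predict(X[tr], y[tr], X[te]), ref.predict(X[te]))

    def test_more_voxels_than_trials_never_crashes(self):
        rng = np.random.default_rng(3)
        y, runs, folds = self._folds(20)
        assert 0.0 <= lda_accuracy(rng.standard_normal((20, 123)), y, folds) <= 1.0


class TestSearchlightMap:
    def _problem(self, shape=(8, 8, 8), n=40, seed=0):
        rng = np.random.default_rng(seed)
        mask = np.zeros(shape, bool)
        mask[1:-1, 1:-1, 1:-1] = True
        y = np.asarray(["a", "b"] * (n // 2))
        runs = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, int(mask.sum())))
        return mask, X, y, runs

    def test_translation_equivariance(self):
        """Shifting mask and data by one voxel shifts the accuracy map."""
        mask, X, y, runs = self._problem()
        m1 = run_searchlight(X, mask, y, runs, radius_mm=4, n_permutations=0)
        shifted = np.roll(mask, 1, axis=0)
        m2 = run_searchlight(X, shifted, y, runs, radius_mm=4, n_permutations=0)
        a1 = m1.accuracy[mask]
        a2 = m2.accuracy[shifted]
        assert np.allclose(a1[np.isfinite(a1)], a2[np.isfinite(a2)], equal_nan=True)

    def test_contiguity_changes_result_on_split_mask(self):
        """Two gray slabs bridged only through the sphere: with filtering the
        far slab's informative voxels cannot help the near centroid."""
        rng = np.random.default_rng(4)
        shape = (7, 9, 9)
        mask = np.zeros(shape, bool)
        mask[1] = True   # slab A
        mask[5] = True   # slab B (gap of 3 > sphere connectivity)
        n = 40
        y = np.asarray(["a", "b"] * (n // 2))
        runs = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, int(mask.sum())))
        cols_b = np.nonzero(np.argwhere(mask)[:, 0] == 5)[0]
        X[np.ix_(y == "a", cols_b)] += 3.0  # signal only in slab B
        smap = run_searchlight(X, mask, y, runs, radius_mm=8, voxel_mm=2, n_permutations=0)
        centroid_a = (1, 4, 4)
        # unfiltered reference at the same centroid: include slab-B voxels
        from speechmvpa.searchlight import build_sphere, lda_accuracy
        from speechmvpa.rfe import leave_run_out_folds

        sphere = build_sphere(8, 2)
        pts = sphere.offsets + centroid_a
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok][mask[tuple(pts[ok].T)]]
        col_of = {tuple(c): i for i, c in enumerate(np.argwhere(mask))}
        cols = [col_of[tuple(p)] for p in pts]
        unfiltered = lda_accuracy(X[:, cols], y, leave_run_out_folds(runs, y))
        assert unfiltered > 0.9                       # slab B drives it
        assert smap.accuracy[centroid_a] < 0.75       # filtered out
        assert smap.n_voxels_used[centroid_a] < len(cols)

    def test_null_data_gives_no_fdr_significant_voxels(self):
        mask, X, y, runs = self._problem(shape=(7, 7, 7), seed=5)
        smap = run_searchlight(X, mask, y, runs, radius_mm=4, n_permutations=30, q=0.05)
        assert smap.q_significant.sum() == 0

    def test_power_monotone_in_planted_effect_size(self):
        """Mean accuracy over planted-region centroids is nondecreasing in
        the planted per-voxel d (within Monte-Carlo error)."""
        from speechmvpa.synth import ExperimentConfig, generate_experiment

        means = []
        for d in (0.0, 0.4, 0.8, 1.2):
            cfg = ExperimentConfig(
                n_runs=2, n_trials_per_run=20, grid_shape=(18, 18, 18), roi_size=3,
                effect_size=d, patterns=(("lip", "voiced-vs-whispered"),), seed=70,
            )
            ds = generate_experiment(cfg)
            from conftest import betas_for

            bsm = betas_for(ds)
            # restrict the map to a neighbourhood of the planted ROI
            roi = ds.roi_mask("lip")
            lo = np.maximum(np.argwhere(roi).min(axis=0) - 2, 0)
            hi = np.argwhere(roi).max(axis=0) + 3
            local = np.zeros_like(ds.gray_mask)
            local[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
            submask = ds.gray_mask & local
            col_of = {tuple(c): i for i, c in enumerate(np.argwhere(ds.gray_mask))}
            cols = [col_of[tuple(c)] for c in np.argwhere(submask)]
            smap = run_searchlight(bsm.values[:, cols], submask, bsm.labels_task,
                                   bsm.runs, n_permutations=0)
            means.append(np.nanmean(smap.accuracy[roi & submask]))
        assert all(b >= a - 0.04 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 0.1

    def test_estimator_interface(self):
        from sklearn.base import clone

        mask, X, y, runs = self._problem(seed=6)
        dec = SearchlightDecoder(radius_mm=4, n_permutations=0)
        clone(dec)
        dec.fit(X, y, runs=runs, mask=mask)
        assert np.isfinite(dec.map_.accuracy[mask]).all()
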