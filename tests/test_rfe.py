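"""Recursive-feature-elimination decoder: schedule, nestedness, null behavior."""

import math

import numpy as np
import pandas as pd
import pytest

from speechmvpa.rfe import (
    RFEConfig,
    RFEDecoder,
    decode_roi,
    group_roi_stats,
    leave_run_out_folds,
    permutation_null,
    rfe_iterate,
    smooth_weight_map,
    train_linear_margin,
)

REDUCED = dict(n_iterations=3, splits_per_elimination=2, n_nested_splits=6, n_permutations=5)


def _noise_problem(n_trials=40, n_vox=60, n_runs=2, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_trials, n_vox))
    y = np.asarray(["a", "b"] * (n_trials // 2))
    runs = np.repeat(np.arange(n_runs), n_trials // n_runs)
    return X, y, runs


class TestFolds:
    def test_one_fold_per_run(self):
        _, y, runs = _noise_problem(n_runs=4, n_trials=40)
        folds = leave_run_out_folds(runs, y)
        assert len(folds) == 4

    def test_two_runs_disjoint_test_sets(self):
        _, y, runs = _noise_problem()
        (tr1, te1), (tr2, te2) = leave_run_out_folds(runs, y)
        assert set(te1).isdisjoint(te2)
        assert set(te1) | set(te2) == set(range(len(y)))

    def test_single_class_run_rejected(self):
        y = np.array(["a"] * 10 + ["a", "b"] * 5)
        runs = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="both classes"):
            leave_run_out_folds(runs, y)


class TestLinearMargin:
    def test_separable_problem_weight_along_class_difference(self):
        X = np.array([[0.0, 0], [0.1, 0], [1.0, 0], [0.9, 0]])
        y = np.array(["a", "a", "b", "b"])
        w, b = train_linear_margin(X, y)
        pred = np.sign(X @ w + b)
        assert len(set(pred[:2])) == 1 and pred[0] != pred[2]
        # weight direction = class-mean difference direction (axis 0)
        assert abs(w[0]) > 100 * abs(w[1])

    def test_label_flip_flips_weight_sign(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 5))
        y = np.array(["a", "b"] * 10)
        w1, _ = train_linear_margin(X, y)
        flipped = np.where(y == "a", "b", "a")
        w2, _ = train_linear_margin(X, flipped)
        cos = w1 @ w2 / (np.linalg.norm(w1) * np.linalg.norm(w2))
        assert cos < -0.999  # antiparallel to solver tolerance

    def test_constant_features_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            train_linear_margin(np.ones((10, 3)), np.array(["a", "b"] * 5))

    def test_null_features_give_chance_cv(self):
        """Labels independent of features: leave-run-out accuracy near 0.5."""
        accs = []
        for seed in range(8):
            X, y, runs = _noise_problem(n_trials=100, n_vox=20, seed=seed)
            for train, test in leave_run_out_folds(runs, y):
                w, b = train_linear_margin(X[train], y[train])
                pred = np.where(X[test] @ w + b > 0, "b", "a")
                accs.append(np.mean(pred == y[test]))
        assert abs(np.mean(accs) - 0.5) < 0.15


class TestSmoothing:
    def test_constant_map_unchanged(self):
        coords = np.argwhere(np.ones((4, 4, 4), bool))
        w = np.full(64, 2.5)
        assert np.allclose(smooth_weight_map(w, coords, (4, 4, 4)), 2.5)

    def test_isolated_voxel_keeps_own_value(self):
        coords = np.array([[0, 0, 0], [10, 10, 10]])
        out = smooth_weight_map(np.array([3.0, 7.0]), coords, (12, 12, 12))
        assert np.allclose(out, [3.0, 7.0])

    def test_single_nonzero_spreads_as_neighborhood_mean(self):
        """Direct enumeration: each survivor's smoothed value is the mean of
        the nonzero weight over its in-mask 3x3x3 neighborhood."""
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 2] = True  # 3x3 slab
        coords = np.argwhere(mask)
        w = np.zeros(len(coords))
        centre = np.nonzero((coords == [2, 2, 2]).all(axis=1))[0][0]
        w[centre] = 9.0
        out = smooth_weight_map(w, coords, (5, 5, 5))
        for i, c in enumerate(coords):
            nbrs = [j for j, c2 in enumerate(coords) if np.max(np.abs(c2 - c)) <= 1]
            assert np.isclose(out[i], w[nbrs].mean())


class TestElimination:
    def test_survivor_schedule_follows_ceil_recursion(self):
        X, y, runs = _noise_problem(n_trials=40, n_vox=1000, seed=2)
        res = decode_roi(X, y, runs, RFEConfig(**REDUCED, rng_seed=0))
        expected, n = [], 1000
        for _ in range(3):
            n = n - math.ceil(0.3 * n)
            expected.append(n)
        for fold_surv in res.survivors:
            assert [len(s) for s in fold_surv] == expected

    def test_survivor_sets_strictly_nested(self):
        X, y, runs = _noise_problem(n_vox=100, seed=3)
        res = decode_roi(X, y, runs, RFEConfig(**REDUCED, rng_seed=1))
        for fold_surv in res.survivors:
            for a, b in zip(fold_surv, fold_surv[1:]):
                assert set(b) < set(a)

    def test_single_voxel_roi_single_iteration(self):
        rng = np.random.default_rng(4)
        cfg = RFEConfig(**REDUCED, rng_seed=0)
        surv, _ = rfe_iterate(
            rng.standard_normal((20, 1)), np.array(["a", "b"] * 10),
            np.array([[0, 0, 0]]), (1, 1, 1), cfg, rng,
        )
        assert len(surv) == 1 and list(surv[0]) == [0]

    def test_informative_voxels_enriched(self):
        """10% planted voxels: final survivor precision beats prevalence."""
        hits = 0
        for seed in range(5):
            X, y, runs = _noise_problem(n_trials=40, n_vox=100, seed=10 + seed)
            X[y == "a", :10] += 1.0
            coords = np.column_stack([np.arange(100) % 5, np.arange(100) // 5 % 5,
                                      np.arange(100) // 25])
            cfg = RFEConfig(**REDUCED, rng_seed=seed, smooth_kernel=1)
            rng = np.random.default_rng(seed)
            surv, _ = rfe_iterate(X, y, coords, (5, 5, 4), cfg, rng)
            final = surv[-1]
            precision = np.mean(final < 10)
            if precision > 0.1:
                hits += 1
        assert hits >= 4

    def test_determinism_under_fixed_seed(self):
        X, y, runs = _noise_problem(seed=5)
        cfg = RFEConfig(**REDUCED, rng_seed=42)
        r1 = decode_roi(X, y, runs, cfg)
        r2 = decode_roi(X, y, runs, cfg)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)
        for f1, f2 in zip(r1.survivors, r2.survivors):
            for s1, s2 in zip(f1, f2):
                assert np.array_equal(s1, s2)


class TestDecoding:
    def test_separable_signal_reaches_perfect_accuracy(self):
        X, y, runs = _noise_problem(n_vox=50, seed=6)
        X[y == "a"] += 4.0
        res = decode_roi(X, y, runs, RFEConfig(**REDUCED, rng_seed=0))
        assert res.final_accuracy == 1.0

    def test_reported_accuracy_matches_plain_cv_on_survivor_set(self):
        """Dual-route check: re-scoring a recorded survivor set with an
        independent plain CV loop reproduces the reported fold accuracy."""
        X, y, runs = _noise_problem(seed=7)
        res = decode_roi(X, y, runs, RFEConfig(**REDUCED, rng_seed=3))
        folds = leave_run_out_folds(runs, y)
        for fi, (train, test) in enumerate(folds):
            keep = res.survivors[fi][0]
            w, b = train_linear_margin(X[np.ix_(train, keep)], y[train])
            # libsvm convention: positive decision values map to classes_[1]
            pred = np.where(X[np.ix_(test, keep)] @ w + b > 0, "b", "a")
            acc = float(np.mean(pred == y[test]))
            assert np.isclose(acc, res.fold_accuracies[fi][0])

    def test_permutation_null_inflated_above_half(self):
        """Max-over-iterations statistic: permuted-label accuracy > 0.5."""
        X, y, runs = _noise_problem(n_trials=40, n_vox=80, seed=8)
        null = permutation_null(
            X, y, runs, RFEConfig(**{**REDUCED, "n_permutations": 24}, rng_seed=1)
        )
        assert null.accuracies.size == 24
        assert null.chance_level > 0.5

    def test_single_permutation_length(self):
        X, y, runs = _noise_problem(seed=9)
        null = permutation_null(X, y, runs, RFEConfig(**{**REDUCED, "n_permutations": 1}))
        assert null.accuracies.size == 1


class TestGroupStats:
    def _table(self, n_sub=6, n_roi=3, delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sub):
            for r in range(n_roi):
                ch = 0.55 + rng.normal(0, 0.02)
                rows.append({"subject": s, "roi": f"roi{r}",
                             "final_accuracy": ch + (delta if r == 0 else 0.0)
                             + rng.normal(0, 0.02),
                             "chance": ch})
        return pd.DataFrame(rows)

    def test_accuracy_equal_chance_nothing_significant(self):
        out = group_roi_stats(self._table(delta=0.0, seed=1))
        assert not out["q_significant"].any()

    def test_planted_roi_detected(self):
        out = group_roi_stats(self._table(delta=0.3, seed=2))
        sig = out.set_index("roi")["q_significant"]
        assert sig["roi0"] and not sig[["roi1", "roi2"]].any()

    def test_mismatched_subjects_rejected(self):
        t = self._table()
        with pytest.raises(ValueError, match="subject sets"):
            group_roi_stats(t.drop(index=0))


def test_estimator_follows_sklearn_conventions():
    from sklearn.base import clone

    dec = RFEDecoder(**REDUCED, rng_seed=1)
    params = dec.get_params()
    assert params["n_iterations"] == 3
    clone(dec)  # must be clonable from constructor params
    X, y, runs = _noise_problem(seed=11)
    dec.fit(X, y, runs=runs)
    assert 0.0 <= dec.final_accuracy_ <= 1.0
    assert len(dec.iteration_accuracy_) == 3
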