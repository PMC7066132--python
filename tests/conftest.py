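import numpy as np
import pytest

from speechmvpa.glm import build_design, extract_trial_features, nuisance_residuals
from speechmvpa.synth import ExperimentConfig, generate_experiment


def betas_for(ds, subject=0, keep_epochs=False):
    """Gray-mask beta-series matrix for one subject of a synthetic dataset."""
    sub = ds.subjects[subject]
    cfg = ds.config
    data = np.concatenate(
        [v.reshape(-1, v.shape[-1]).T for v in sub.volumes], axis=0
    )[:, ds.gray_mask.reshape(-1)]
    design = build_design(
        sub.trial_table, np.vstack(sub.motion), cfg.n_vols_per_run, cfg.tr_s, cfg.drift_order
    )
    resid = nuisance_residuals(data, design)
    return extract_trial_features(
        resid, sub.trial_table, design, np.argwhere(ds.gray_mask), keep_epochs=keep_epochs
    )


def gray_columns(ds):
    return {tuple(c): i for i, c in enumerate(np.argwhere(ds.gray_mask))}


@pytest.fixture(scope="session")
def planted_ds():
    """Small session with planted task and place-of-articulation patterns."""
    cfg = ExperimentConfig(
        n_runs=2, n_trials_per_run=20, grid_shape=(18, 18, 18), roi_size=3,
        effect_size=1.2, seed=11,
    )
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def planted_betas(planted_ds):
    return betas_for(planted_ds)


@pytest.fixture(scope="session")
def null_ds():
    """Signal-free session (effect_size=0, no couplings)."""
    cfg = ExperimentConfig(
        n_runs=2, n_trials_per_run=20, grid_shape=(18, 18, 18), roi_size=3,
        effect_size=0.0, seed=12,
    )
    return generate_experiment(cfg)
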