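# speechmvpa

Decoding and connectivity analysis of sparse-sampled speech-production
fMRI, with a fully synthetic ground-truth generator so every stage of the
pipeline can be validated without access to human data.

## Who this is for

Researchers analysing slow event-related, sparse-sampled speech fMRI
(TR 2 s with a silent production gap), who want to:

* estimate **single-trial response amplitudes** ("beta series") from
  first-level GLM residuals;
* decode articulatory or phonatory conditions inside anatomical ROIs with
  **recursive feature elimination** (RFE) around a linear SVM;
* map decodable information across cortex with a **contiguity-filtered
  searchlight** (linear discriminant analysis);
* measure task-state **functional connectivity** by correlating beta
  series against a seed region;
* extract **acoustic** (envelope, loudness, spectrogram, F1/F2 formants)
  and **physiological** (respiration, chin pressure) measures that verify
  the experimental design.

## The methods in brief

**Beta series.** Each voxel's time series is residualised against per-run
Legendre drift polynomials (orders 0–5), six realignment parameters and
per-volume censoring indicators (motion derivative norm > 0.4 mm).  For
each trial the 16 s epoch (9 TR-grid samples) locked to trial onset is
demeaned, detrended for a linear slope, and summarised as the mean over
the HRF peak window (lags 4–10 s), giving a trials × voxels matrix `B`.

**RFE decoding.** Within each leave-run-out training fold, 40 resamples
(ratio 0.9, with replacement, class-stratified) are classified with a
soft-margin linear SVM; every 4th resample the signed weights are
averaged, smoothed with a 3×3×3 box restricted to surviving voxels, and
the 30 % of voxels with smallest |weight| are removed
(`n_k = n_{k-1} − ⌈0.3 n_{k-1}⌉`).  After 10 eliminations, each surviving
set is scored on the held-out run; the ROI accuracy is the **maximum**
over iterations of the fold-averaged accuracy.  Because that maximum
inflates chance above 0.5, the null is the same procedure repeated under
within-run label permutation; group inference tests accuracy against the
permutation mean, FDR-corrected across ROIs (BH, q < 0.05).

**Searchlight.** A 7 mm sphere (123 voxels at 2 mm) is centred on every
gray-matter voxel, intersected with the gray mask, and reduced to the
26-connected component containing the centroid (so volumetrically close
but topographically distant cortex is not mixed).  Each sphere is decoded
with a shrinkage-regularised LDA under leave-run-out cross-validation;
binary chance is 0.5.

**Beta-series connectivity.** The seed's mean beta series is Pearson-
correlated with every voxel, Fisher-transformed (`z = atanh r`), and
tested against zero across subjects; condition-specific coupling is the
paired contrast of condition-subset z-maps.

**Synthetic ground truth.** `speechmvpa.synth` generates complete
sessions — 4D volumes with HRF-convolved condition patterns of known
per-voxel Cohen's d planted inside chosen ROIs, Legendre drift, motion
spikes, a global respiratory component (gamma kernel, peak 8 s),
trial-gain couplings between regions, 1000 Hz respiration/chin-pressure
traces and 22 400 Hz vowel-like audio with known formants.

## Worked example

```python
import numpy as np
from speechmvpa import ExperimentConfig, generate_experiment, RFEConfig, decode_roi
from speechmvpa.rfe import permutation_null
from speechmvpa.glm import build_design, nuisance_residuals, extract_trial_features

cfg = ExperimentConfig(n_runs=2, n_trials_per_run=20, grid_shape=(18, 18, 18),
                       roi_size=3, effect_size=1.2, seed=11)
ds = generate_experiment(cfg)          # volumes, events, motion, physio, truth
sub = ds.subjects[0]

data = np.concatenate([v.reshape(-1, v.shape[-1]).T for v in sub.volumes]
                      )[:, ds.gray_mask.reshape(-1)]
design = build_design(sub.trial_table, np.vstack(sub.motion),
                      cfg.n_vols_per_run, cfg.tr_s)
betas = extract_trial_features(nuisance_residuals(data, design),
                               sub.trial_table, design)

col = {tuple(c): i for i, c in enumerate(np.argwhere(ds.gray_mask))}
coords = np.argwhere(ds.roi_mask("larynx") & ds.gray_mask)
X = betas.values[:, [col[tuple(c)] for c in coords]]
rfe = RFEConfig(n_iterations=3, splits_per_elimination=2, n_nested_splits=6,
                n_permutations=10, rng_seed=0)
res = decode_roi(X, betas.labels_task, betas.runs, rfe, coords, ds.gray_mask.shape)
null = permutation_null(X, betas.labels_task, betas.runs, rfe, coords, ds.gray_mask.shape)
print(f"accuracy {res.final_accuracy:.3f}  chance {null.chance_level:.3f}  "
      f"p {null.p_value(res.final_accuracy):.3f}")
```

Output:

```
accuracy 1.000  chance 0.568  p 0.091
```

The planted voiced-vs-whispered pattern in the "larynx" ROI (per-voxel
d = 1.2) is decoded perfectly, far above the *permutation* chance of
0.568 — note how the max-over-iterations statistic inflates chance above
the theoretical 0.5, which is exactly why the permutation null is
required.  (With 10 permutations the smallest attainable p is 1/11.)

The same analysis end-to-end from a shell:

```bash
speechmvpa run --out demo_run --seed 7          # synth → … → report
cat demo_run/report/report.md
```

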