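# Methods

This note documents the models, numerical conventions and design choices
behind `speechmvpa`, and what its synthetic-data validation does and does
not establish.

## The experimental design being modelled

The package targets sparse-sampled, slow event-related speech-production
fMRI: TR 2 s with a 0.9 s silent gap in which the participant speaks
(avoiding scanner noise, the Lombard reflex, and speech-locked motion in
the acquisition window); trials every 16 s; three utterances per trial
(one per TR, i.e. a 6 s production block); 10 condition types — 2 tasks
(voiced, whispered) × 5 items (`bb`, `dd`, `mm`, `nn`, schwa); four runs
per session.  All defaults in `ExperimentConfig` encode these values.

## First-level model and beta series

* **HRF**: canonical double-gamma, gamma-density peak at 6 (unit scale)
  minus undershoot at 16 divided by 6, normalised to peak 1 so amplitudes
  are peak signal change.  Trials are 6 s boxcars convolved on a 50 ms
  grid and sampled at TR resolution.
* **Nuisance**: Legendre polynomials of order 0–5 per run, six motion
  parameters, and one indicator column per censored volume.  A volume is
  censored when the Euclidean norm of the motion-parameter derivative
  exceeds 0.4 mm, with a strict `>` at the boundary; the first volume is
  never censored.  Censoring by indicator columns (not row deletion)
  keeps the residual series on the TR grid.
* **Epoch convention**: the trial epoch is 9 samples at lags 0, 2, …,
  16 s.  Sixteen seconds at TR 2 spans 8 intervals; taking 9 samples
  means the last sample coincides with the next trial's onset volume.
  We accept that one-sample overlap and document it rather than guess a
  different grid.
* **Epoch → scalar**: each epoch is demeaned, detrended for a linear
  slope, and averaged over lags 2–5 (4–10 s), the HRF peak window.  The
  whole map from epoch to scalar is a fixed linear functional
  (`glm.epoch_summary_vector`), which the generator reuses to calibrate
  planted effect sizes exactly.  The full 9-lag vector is available via
  `keep_epochs=True` for sensitivity analyses.
* Trials with more than 1/3 of their epoch censored, or whose epoch runs
  past the end of the run, are dropped and reported.

## RFE decoding

Schedule: within each leave-run-out training fold, `n_nested_splits=40`
class-stratified resamples of ratio 0.9 drawn *with replacement*; a linear
SVM per resample; every `splits_per_elimination=4` resamples the signed
weights of that window are averaged (windowed, not cumulative), smoothed
with a 3×3×3 box mean restricted to the surviving voxels, and the
`elim_fraction=30 %` of voxels with smallest |smoothed weight| removed,
`ceil` on the count, ties broken by voxel index for determinism.  Ten
eliminations yield ten strictly nested voxel sets; each is scored by
retraining on the full training data (the resamples are used only for
ranking) and testing the held-out run.  The final statistic is the
maximum over iterations of the fold-averaged accuracy.

**Chance level.**  The max statistic makes 0.5 the wrong reference: on
label-permuted data the same procedure averages ≈ 0.55 at desk scale.
All inference therefore uses the permutation null — labels shuffled
within run (preserving run-level exchangeability and leave-run-out
validity), the entire RFE procedure repeated, and the subject's accuracy
compared to the permutation mean.  Group inference is a paired t of
accuracy vs. chance per ROI, BH-FDR over ROIs at q = 0.05.

**Classifier.**  libsvm's SMO with a linear kernel.  The training
misclassification budget `slack_fraction` (default 5 %) sets the slack
penalty as `C = 1/slack_fraction`.  We deliberately do not use the
nu-SVM parameterisation: at nu = 0.05 on non-separable resamples the
nu-SVC optimum is degenerate — the recovered weight vector depends on
sample order and label-flip antisymmetry fails — whereas the C-form
solution is unique and stable, and smaller budgets still drive the fit
toward a hard margin.

## Searchlight

Sphere: all integer offsets with Euclidean norm ≤ ⌊radius/voxel⌋ voxels
(7 mm at 2 mm ⇒ norm ≤ 3, 123 offsets, "three voxels in every direction
plus the centroid").  Edge spheres are truncated by the mask, never
padded.  The masked sphere is split into 26-connected components and
only the centroid's component is retained, so a sphere straddling two
topographically distant gray-matter folds decodes only the centroid's
fold.  Spheres reduced below 2 voxels are skipped and flagged.

Classifier: linear discriminant with Ledoit–Wolf shrinkage of the pooled
covariance (`lsqr` solver), because spheres routinely hold more voxels
than training trials; the shrinkage makes the fit well-posed without a
tunable parameter.  Per-voxel p-values come from within-run label
permutations; BH-FDR is applied across computed voxels.  Group mode is a
per-voxel t of subject accuracies against chance (0.5 or a permutation
estimate), then FDR.

## Beta-series connectivity

Seed = largest 26-connected suprathreshold cluster of the subject-level
localizer contrast (two-sample t on beta series, uncorrected two-tailed
p < 0.05, positive direction) inside an anatomical mask; subjects with
no suprathreshold voxel are flagged and excluded.  The seed's mean beta
series is Pearson-correlated with every voxel; r is clipped to
±(1 − 1e−7) before `atanh` (so a voxel identical to the seed maps to a
finite guard value ≈ 8.1, flagged rather than infinite); zero-variance
voxels are recorded as missing.  Group maps: one-sample two-sided t of z
against 0; condition-specific coupling: paired t of condition-subset
z-maps.  Seed voxels are excluded from inference summaries.

## Synthetic data: what is emulated

Per run the generator composes, on a 24³ grid of 2 mm voxels (defaults):

* i.i.d. Gaussian voxel noise (`noise_sd`, default 1.0 signal units);
* shared low-frequency drift: Legendre orders 1–5 with N(0, 0.5²)
  coefficients — exactly the structure the nuisance model assumes;
* a global respiratory component added to all gray-matter voxels: one
  gamma kernel per trial (shape 5, mode at `resp_irf_peak_s = 8 s`),
  amplitude 0.5 — this is what the trial-locked gray-matter average
  (resp-IRF) recovers;
* planted multivoxel patterns: for a chosen ROI and condition contrast,
  each informative voxel gets a fixed ± amplitude whose sign follows the
  trial's class.  The amplitude is calibrated through the epoch-summary
  functional so that the realised per-voxel Cohen's d *of the extracted
  features* equals `effect_size`; with no quantitative effect size
  published for this paradigm, d is a free parameter (default 1);
* trial-gain couplings: seed and coupled ROIs share a common evoked
  response scaled by a per-trial gain g ~ N(1, 0.3); restricting the
  shared gain to a condition subset creates condition-specific coupling,
  independent gains elsewhere;
* motion: random walks (step SD 0.02 mm) plus spike jumps of 0.6 mm at
  rate 2 % of volumes, to exercise censoring;
* physio at 1000 Hz: per trial an inhalation bump peaking 0.6 s after
  onset (before the first utterance at 1.1 s) and a slow exhalation;
  chin-pressure bumps at each utterance; amplitudes jitter identically
  across conditions, making voiced/whispered traces exchangeable by
  construction; both channels are 10 Hz low-passed;
* audio at 22 400 Hz: two-resonator all-pole synthesis per item with
  known (F1, F2); voiced uses a 120 Hz impulse train at higher amplitude,
  whispered a noise source with F1 raised 150 Hz — reproducing the
  qualitative loudness and F1 signatures of whispered speech.

**What it does not emulate**: spatially correlated physiological noise,
vascular structure, anatomically realistic geometry or surfaces,
between-subject anatomical variability (all subjects share one grid),
scanner drifts beyond order-5 polynomials.  Passing tests therefore
demonstrate the correctness and calibration of the *analysis machinery*
under the stated noise model, not performance on real tissue.

## Acoustic measures

Envelope: zero-phase (filtfilt) Butterworth order-4 high-pass at 150 Hz,
Hilbert analytic magnitude, zero-phase order-4 low-pass at 8 Hz; the
two-pass implementation doubles the effective order, which is intended.
Loudness: mean |signal| in the 100 ms window centred on the envelope
peak (earliest-sample tie-break, edge truncation).  Spectrogram:
100-sample periodic Hann segments, hop 10 (90 % overlap), 128 one-sided
frequency bins.  Formants: autocorrelation LPC of order
2 + round(fs/1000) on a Hamming-windowed segment, roots with positive
imaginary part converted to Hz, restricted to (90 Hz, Nyquist − 50 Hz)
with bandwidth < 400 Hz, sorted; degenerate inputs return a failure flag
rather than numbers.  Formants are estimated from the waveform directly:
linear prediction operates on the time signal, not on the spectrogram
image.

## Statistical kernel

BH step-up FDR in the independence/PRDS form (the plain "FDR" of the
analysis); two-tailed t-tests throughout; permutations always within
run.  Zero-variance degenerate cases are flagged (t = ±inf or 0) instead
of propagating NaN.  Every stochastic routine takes an explicit seed and
the pipeline derives all stage seeds from one master seed, recorded in
the run manifest.

## Validation problem sizes

The test suite validates at desk scale, chosen to finish on one CPU in
minutes while keeping each statistical check properly powered: null
calibration of the searchlight LDA uses 125 spheres × 20 permutations of
a 4-run signal-free session; max-statistic calibration uses 200
replicates of a 200-voxel ROI at a shortened elimination schedule
(5 × 2 splits — the rank-uniformity property being tested is
schedule-invariant); ROI power/specificity uses 20 replicates of 20
subjects with d = 1 in one of 8 ROIs and 2 permutations per chance
estimate (the permutation mean is unbiased at any count); connectivity
recovery uses 20 replicates of 12 subjects — at
smaller group sizes the 7-df group t on Fisher-z differences is visibly
heavy-tailed and a whole-brain FDR search will find its tails, so the
group size is chosen for calibration of the t model, not for effect
detection.  Empirical permutation p-values are discrete (11 support
points at 10 permutations); uniformity is therefore assessed on the
standard randomized construction, which is exactly U(0,1) under
exchangeability.

## Known limitations

* Volumetric group analysis on a shared grid; surface-based alignment
  and cerebellar flatmaps are out of scope.
* No autocorrelation modelling / prewhitening in the GLM.
* Binary decoding only; the elimination procedure is specific to the
  windowed-averaging schedule described above.
* The CLI's caching is digest-based at stage granularity; it re-executes
  a whole stage when any input digest changes.
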