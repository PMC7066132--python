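"""Synthetic speech-production fMRI experiments with planted ground truth.

Emulates the sparse-sampled slow event-related design of the study the
package targets: TR 2 s with a 0.9 s silent production gap, trials every
16 s containing three utterances, 10 condition types (voiced/whispered x
five disyllabic items), four runs.  Every component a downstream stage
must recover is planted explicitly and recorded in :class:`GroundTruth`:

* multivoxel condition patterns confined to named box ROIs, calibrated so
  the realised per-voxel Cohen's d *in beta-series feature space* equals
  the requested ``effect_size``;
* a global respiratory signal in gray matter, one gamma kernel (default
  peak 8 s) per trial;
* shared low-frequency Legendre drift and per-voxel Gaussian noise;
* motion random walks with occasional super-threshold spikes;
* trial-level gain couplings between a seed ROI and remote ROIs (the
  beta-series connectivity target);
* respiration/chin-pressure traces at 1000 Hz and vowel-like utterance
  audio at 22400 Hz whose all-pole resonances are the formant ground
  truth.

Identical config + seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .glm import CONDITIONS, TASKS, contrast_vector, epoch_summary_vector
from .hrf import respiratory_kernel, trial_response

__all__ = [
    "ExperimentConfig",
    "GroundTruth",
    "PhysioTrace",
    "SubjectData",
    "SyntheticDataset",
    "make_box_rois",
    "generate_experiment",
    "plant_pattern",
    "generate_physio",
    "generate_utterance_audio",
    "utterance_formants",
    "write_dataset",
]

ROI_NAMES = ("lip", "tongue", "larynx", "jaw", "velum", "resp", "ctrl1", "ctrl2")


@dataclass
class ExperimentConfig:
    """Parameters of a synthetic session.

    Design defaults mirror the emulated study (4 runs, TR 2 s, 0.9 s gap,
    ITI 16 s, 3 utterances/trial, 2 mm voxels, drift order 5); amplitudes
    and grid size are generator choices documented in the methods note.
    """

    n_subjects: int = 1
    n_runs: int = 4
    n_trials_per_run: int = 30
    tr_s: float = 2.0
    silent_gap_s: float = 0.9
    iti_s: float = 16.0
    utterances_per_trial: int = 3
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_mm: float = 2.0
    noise_sd: float = 1.0
    drift_order: int = 5
    drift_sd: float = 0.5
    resp_amp: float = 0.5
    resp_irf_peak_s: float = 8.0
    hrf_peak_delay_s: float = 6.0       # mismatch knob for robustness tests
    effect_size: float = 1.0            # per-voxel Cohen's d in feature space
    informative_frac: float = 1.0       # fraction of ROI voxels carrying pattern
    patterns: tuple[tuple[str, str], ...] = (
        ("lip", "bilabial-vs-alveolar"),
        ("larynx", "voiced-vs-whispered"),
    )
    couplings: tuple[tuple[str, str], ...] = ()   # (seed ROI, coupled ROI)
    coupling_gain_sd: float = 0.3
    coupling_amp_d: float = 3.0         # evoked amplitude, in feature-noise SDs
    coupling_conditions: tuple[str, ...] | None = None
    roi_size: int = 5
    motion_walk_sd: float = 0.02
    motion_spike_rate: float = 0.02
    physio_fs_hz: int = 1000
    audio_fs_hz: int = 22400
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_runs", "n_trials_per_run", "utterances_per_trial"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        ratio = self.iti_s / self.tr_s
        if not np.isclose(ratio, round(ratio)):
            raise ValueError("iti_s must be an integer multiple of tr_s")
        if self.n_trials_per_run % len(CONDITIONS):
            raise ValueError(
                f"n_trials_per_run must be a multiple of {len(CONDITIONS)} "
                "so every condition type appears equally often per run"
            )

    @property
    def vols_per_trial(self) -> int:
        return int(round(self.iti_s / self.tr_s))

    @property
    def n_vols_per_run(self) -> int:
        # one trailing volume so the last trial's 9-sample epoch fits
        return self.n_trials_per_run * self.vols_per_trial + 1


@dataclass
class GroundTruth:
    """Everything planted, for recovery checks."""

    effect_size: float
    pattern_maps: dict[str, np.ndarray]        # contrast kind -> 3D weight map
    pattern_rois: dict[str, str]               # contrast kind -> roi name
    seed_regions: dict[str, np.ndarray]        # roi name -> boolean 3D mask
    coupled_regions: dict[str, np.ndarray]
    resp_irf_peak_s: float
    feature_noise_sd: float                    # ||c|| * noise_sd
    feature_gain: float                        # c . unit HRF epoch response


@dataclass
class PhysioTrace:
    """Respiration + chin pressure at ``fs_hz`` with TR trigger indices."""

    fs_hz: int
    respiration: np.ndarray
    chin_pressure: np.ndarray
    tr_triggers: np.ndarray

    def __post_init__(self):
        if self.respiration.shape != self.chin_pressure.shape:
            raise ValueError("physio series lengths must match")


@dataclass
class SubjectData:
    volumes: list[np.ndarray]         # per run, (nx, ny, nz, n_vols) float32
    motion: list[np.ndarray]          # per run, (n_vols, 6)
    trial_table: pd.DataFrame         # all runs; onset_s is within-run time
    physio: list[PhysioTrace]


@dataclass
class SyntheticDataset:
    config: ExperimentConfig
    affine: np.ndarray
    gray_mask: np.ndarray             # boolean 3D
    roi_labels: np.ndarray            # int 3D, 0 = background
    roi_names: dict[str, int]
    subjects: list[SubjectData]
    ground_truth: GroundTruth

    def roi_mask(self, name: str) -> np.ndarray:
        return self.roi_labels == self.roi_names[name]


# --------------------------------------------------------------------------
# spatial layout

def make_box_rois(
    grid_shape: tuple[int, int, int], roi_size: int = 5, names: tuple[str, ...] = ROI_NAMES
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Gray-matter mask plus up to 8 disjoint box ROIs on an octant lattice.

    The gray mask is the central box (one sixth margin per axis); ROIs are
    ``roi_size``-cubes placed at the octant corners inside it.
    """
    shape = tuple(int(s) for s in grid_shape)
    lo = [max(1, s // 6) for s in shape]
    hi = [s - max(1, s // 6) for s in shape]
    gray = np.zeros(shape, dtype=bool)
    gray[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True

    if any(hi[a] - lo[a] < 2 * roi_size + 1 for a in range(3)):
        raise ValueError(
            f"grid {shape} too small for {roi_size}-voxel ROIs inside the gray box"
        )
    labels = np.zeros(shape, dtype=np.int16)
    roi_names: dict[str, int] = {}
    corners = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    for li, (name, (i, j, k)) in enumerate(zip(names, corners), start=1):
        starts = [
            lo[a] + 1 + (0 if c == 0 else hi[a] - lo[a] - roi_size - 2)
            for a, c in enumerate((i, j, k))
        ]
        sl = tuple(slice(s, s + roi_size) for s in starts)
        labels[sl] = li
        roi_names[name] = li
    return gray, labels, roi_names


# --------------------------------------------------------------------------
# trial table and motion

def _make_trial_table(cfg: ExperimentConfig, rng: np.random.Generator) -> pd.DataFrame:
    reps = cfg.n_trials_per_run // len(CONDITIONS)
    rows = []
    for run in range(cfg.n_runs):
        conds = np.array(CONDITIONS * reps)
        conds = conds[rng.permutation(conds.size)]  # blocked shuffle per run
        for t_idx, cond in enumerate(conds):
            task, item = cond.split("_")
            rows.append((t_idx * cfg.iti_s, run, task, item))
    return pd.DataFrame(rows, columns=["onset_s", "run", "task", "item"])


def _make_motion(cfg: ExperimentConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_vols_per_run
    steps = rng.normal(0.0, cfg.motion_walk_sd, size=(n, 6))
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)
    spikes = rng.random(n) < cfg.motion_spike_rate
    spikes[0] = False
    for v in np.nonzero(spikes)[0]:
        motion[v:, int(rng.integers(6))] += 0.6  # step jump > 0.4 mm derivative
    return motion


# --------------------------------------------------------------------------
# signal planting

def _contrast_signs(trial_table: pd.DataFrame, kind: str) -> np.ndarray:
    c = contrast_vector(kind)
    cond_idx = {cond: i for i, cond in enumerate(CONDITIONS)}
    conds = (trial_table["task"] + "_" + trial_table["item"]).map(cond_idx).to_numpy()
    return np.sign(c[conds])


def _add_trial_responses(run_vol: np.ndarray, flat_weights: np.ndarray,
                         amplitudes: np.ndarray, starts: np.ndarray,
                         unit_resp: np.ndarray) -> None:
    """In-place: add ``amp_i * weight_v * unit_resp`` at each trial start.

    ``run_vol`` is (n_vols, n_sel_voxels); ``flat_weights`` (n_sel,);
    ``amplitudes`` (n_trials,); ``starts`` volume indices.
    """
    n_vols = run_vol.shape[0]
    for amp, s in zip(amplitudes, starts):
        if amp == 0.0:
            continue
        stop = min(n_vols, s + unit_resp.size)
        run_vol[s:stop] += amp * unit_resp[: stop - s, None] * flat_weights[None, :]


def plant_pattern(
    volumes: list[np.ndarray],
    trial_table: pd.DataFrame,
    roi_voxels: np.ndarray,
    contrast: np.ndarray,
    effect_size: float,
    noise_sd: float,
    tr_s: float = 2.0,
    seed: int | np.random.Generator = 0,
    informative_frac: float = 1.0,
    hrf_peak_delay_s: float = 6.0,
) -> np.ndarray:
    """Add a fixed multivoxel pattern whose sign follows the trial class.

    ``contrast`` is a per-trial labelling in {-1, 0, +1}; each informative
    ROI voxel receives ``+/- a`` per trial where the amplitude ``a`` is
    calibrated so that the realised per-voxel Cohen's d of the extracted
    beta-series features equals ``effect_size``.  Modifies ``volumes`` in
    place and returns the planted 3D weight map.
    """
    roi_voxels = np.asarray(roi_voxels, dtype=bool)
    if not roi_voxels.any():
        raise ValueError("roi_voxels is empty")
    contrast = np.asarray(contrast, dtype=float)
    if not ((contrast > 0).any() and (contrast < 0).any()):
        raise ValueError("contrast must label both classes")
    rng = np.random.default_rng(seed)

    c = epoch_summary_vector()
    unit = trial_response(tr_s=tr_s, n_vols=17, peak_delay_s=hrf_peak_delay_s)
    gain = float(c @ unit[: c.size])
    s_f = noise_sd * float(np.linalg.norm(c))
    amp = effect_size * s_f / (2.0 * gain) if noise_sd > 0 else effect_size

    coords = np.argwhere(roi_voxels)
    n_inf = max(1, int(round(informative_frac * coords.shape[0])))
    chosen = coords[rng.choice(coords.shape[0], size=n_inf, replace=False)]
    signs = rng.choice([-1.0, 1.0], size=n_inf)

    weight_map = np.zeros(roi_voxels.shape)
    weight_map[tuple(chosen.T)] = signs * amp

    if effect_size != 0.0:
        for run, grp in trial_table.groupby("run"):
            vol4d = volumes[int(run)]
            sel = np.ascontiguousarray(vol4d[tuple(chosen.T)].T)  # (n_vols, n_inf)
            starts = np.round(grp["onset_s"].to_numpy() / tr_s).astype(int)
            amps = contrast[grp.index.to_numpy()] * 1.0
            _add_trial_responses(sel, signs * amp, amps, starts, unit)
            vol4d[tuple(chosen.T)] = sel.T
    return weight_map


# --------------------------------------------------------------------------
# experiment generation

def generate_experiment(config: ExperimentConfig) -> SyntheticDataset:
    """Build a full synthetic session per subject; see module docstring."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gray, roi_labels, roi_names = make_box_rois(cfg.grid_shape, cfg.roi_size)
    for name, _ in cfg.patterns:
        if name not in roi_names:
            raise ValueError(f"pattern ROI {name!r} not in layout {sorted(roi_names)}")

    affine = np.diag([cfg.voxel_mm] * 3 + [1.0])
    c = epoch_summary_vector()
    unit = trial_response(
        tr_s=cfg.tr_s, n_vols=cfg.vols_per_trial * 2 + 1, peak_delay_s=cfg.hrf_peak_delay_s
    )
    gain = float(c @ unit[: c.size])
    s_f = cfg.noise_sd * float(np.linalg.norm(c))

    resp_t = np.arange(cfg.vols_per_trial * 3 + 1) * cfg.tr_s
    resp_unit = respiratory_kernel(resp_t, cfg.resp_irf_peak_s)

    gray_flat = np.nonzero(gray.reshape(-1))[0]
    n_vox = int(np.prod(cfg.grid_shape))
    n_vols = cfg.n_vols_per_run

    pattern_maps: dict[str, np.ndarray] = {}
    pattern_rois: dict[str, str] = {}
    subjects: list[SubjectData] = []

    # one fixed pattern per contrast, shared across subjects (somatotopy is
    # anatomically consistent); amplitude as in plant_pattern
    pat_rng = np.random.default_rng(rng.integers(2**31))
    amp = cfg.effect_size * s_f / (2.0 * gain) if cfg.noise_sd > 0 else cfg.effect_size
    for roi_name, kind in cfg.patterns:
        mask = roi_labels == roi_names[roi_name]
        coords = np.argwhere(mask)
        n_inf = max(1, int(round(cfg.informative_frac * coords.shape[0])))
        chosen = coords[pat_rng.choice(coords.shape[0], size=n_inf, replace=False)]
        wmap = np.zeros(cfg.grid_shape)
        wmap[tuple(chosen.T)] = pat_rng.choice([-1.0, 1.0], size=n_inf) * amp
        pattern_maps[kind] = wmap
        pattern_rois[kind] = roi_name

    coup_amp = cfg.coupling_amp_d * s_f / gain if cfg.noise_sd > 0 else cfg.coupling_amp_d
    seed_regions = {s: roi_labels == roi_names[s] for s, _ in cfg.couplings}
    coupled_regions = {t: roi_labels == roi_names[t] for _, t in cfg.couplings}

    for _ in range(cfg.n_subjects):
        tt = _make_trial_table(cfg, rng)
        vols, motions, physios = [], [], []
        for run in range(cfg.n_runs):
            grp = tt[tt["run"] == run]
            starts = np.round(grp["onset_s"].to_numpy() / cfg.tr_s).astype(int)

            data = rng.normal(0.0, cfg.noise_sd, size=(n_vols, n_vox))

            # shared Legendre drift (orders 1..drift_order; 0 is baseline)
            x = np.linspace(-1, 1, n_vols)
            coeffs = rng.normal(0.0, cfg.drift_sd, size=cfg.drift_order)
            drift = sum(
                co * np.polynomial.legendre.Legendre.basis(k + 1)(x)
                for k, co in enumerate(coeffs)
            )
            data += drift[:, None]

            # global respiratory component in gray matter
            if cfg.resp_amp != 0.0:
                resp_ts = np.zeros(n_vols)
                for s in starts:
                    stop = min(n_vols, s + resp_unit.size)
                    resp_ts[s:stop] += resp_unit[: stop - s]
                data[:, gray_flat] += cfg.resp_amp * resp_ts[:, None]

            # planted condition patterns
            for kind, wmap in pattern_maps.items():
                signs = _contrast_signs(grp, kind)
                w_flat = wmap.reshape(-1)
                sel = np.nonzero(w_flat)[0]
                for amp_i, s in zip(signs, starts):
                    if amp_i == 0.0:
                        continue
                    stop = min(n_vols, s + unit.size)
                    data[s:stop, sel] += amp_i * unit[: stop - s, None] * w_flat[sel][None, :]

            # trial-gain couplings (beta-series connectivity ground truth)
            if cfg.couplings:
                in_subset = (
                    np.ones(len(grp), dtype=bool)
                    if cfg.coupling_conditions is None
                    else (grp["task"] + "_" + grp["item"]).isin(cfg.coupling_conditions).to_numpy()
                )
                shared = rng.normal(1.0, cfg.coupling_gain_sd, size=len(grp))
                for seed_name, targ_name in cfg.couplings:
                    for mask, independent in (
                        (seed_regions[seed_name], False),
                        (coupled_regions[targ_name], True),
                    ):
                        gains = shared.copy()
                        if independent:
                            indep = rng.normal(1.0, cfg.coupling_gain_sd, size=len(grp))
                            gains = np.where(in_subset, shared, indep)
                        sel = np.nonzero(mask.reshape(-1))[0]
                        for g_i, s in zip(gains, starts):
                            stop = min(n_vols, s + unit.size)
                            data[s:stop, sel] += coup_amp * g_i * unit[: stop - s, None]

            vols.append(
                np.ascontiguousarray(
                    data.T.reshape(cfg.grid_shape + (n_vols,)).astype(np.float32)
                )
            )
            motions.append(_make_motion(cfg, rng))
            physios.append(generate_physio(grp, cfg, rng))
        subjects.append(SubjectData(vols, motions, tt, physios))

    gt = GroundTruth(
        effect_size=cfg.effect_size,
        pattern_maps=pattern_maps,
        pattern_rois=pattern_rois,
        seed_regions=seed_regions,
        coupled_regions=coupled_regions,
        resp_irf_peak_s=cfg.resp_irf_peak_s,
        feature_noise_sd=s_f,
        feature_gain=gain,
    )
    return SyntheticDataset(cfg, affine, gray, roi_labels, roi_names, subjects, gt)


# --------------------------------------------------------------------------
# physiological traces

def generate_physio(
    trial_table: pd.DataFrame,
    config: ExperimentConfig,
    rng: int | np.random.Generator = 0,
) -> PhysioTrace:
    """Respiration and chin-pressure traces for one run at 1000 Hz.

    Each trial contributes an inhalation bump peaking ~0.6 s after trial
    onset — before the first utterance (which falls in the 0.9 s silent gap,
    1.1 s after each TR onset) — followed by a slow exhalation through the
    three productions.  Chin pressure deflects at each utterance.  Trial
    amplitudes jitter randomly but identically for voiced and whispered
    trials, so the two conditions are exchangeable by construction.
    """
    rng = np.random.default_rng(rng)
    cfg = config
    fs = cfg.physio_fs_hz
    n_vols = cfg.n_vols_per_run
    n_samp = int(n_vols * cfg.tr_s * fs)
    t = np.arange(n_samp) / fs

    resp = np.zeros(n_samp)
    chin = np.zeros(n_samp)
    utter_offsets = [
        u * cfg.tr_s + (cfg.tr_s - cfg.silent_gap_s) + 0.25
        for u in range(cfg.utterances_per_trial)
    ]
    for onset in trial_table["onset_s"].to_numpy():
        amp = rng.normal(1.0, 0.1)
        resp += amp * np.exp(-(((t - onset - 0.6) / 0.8) ** 2))
        resp -= 0.6 * amp * np.exp(-(((t - onset - 3.8) / 2.2) ** 2))
        chin_amp = rng.normal(1.0, 0.1)
        for uo in utter_offsets:
            chin += chin_amp * np.exp(-(((t - onset - uo) / 0.12) ** 2))
    resp += rng.normal(0.0, 0.02, n_samp)
    chin += rng.normal(0.0, 0.02, n_samp)
    # 10 Hz low-pass, as applied by the recording chain
    sos = _sig.butter(4, 10.0, btype="low", fs=fs, output="sos")
    resp = _sig.sosfiltfilt(sos, resp)
    chin = _sig.sosfiltfilt(sos, chin)
    triggers = np.arange(n_vols) * int(cfg.tr_s * fs)
    return PhysioTrace(fs, resp, chin, triggers)


# --------------------------------------------------------------------------
# utterance audio

_FORMANT_TABLE = {
    "bb": (420.0, 1100.0),
    "dd": (400.0, 1700.0),
    "mm": (380.0, 1300.0),
    "nn": (400.0, 1500.0),
    "schwa": (500.0, 1500.0),
}
_WHISPER_F1_SHIFT = 150.0   # whispered vowels show a raised F1
_VOICED_AMP = 0.9
_WHISPER_AMP = 0.25


def utterance_formants(item: str, task: str) -> tuple[float, float]:
    """Ground-truth (F1, F2) of a synthetic utterance."""
    if item not in _FORMANT_TABLE:
        raise ValueError(f"unknown item {item!r}")
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    f1, f2 = _FORMANT_TABLE[item]
    if task == "whispered":
        f1 += _WHISPER_F1_SHIFT
    return f1, f2


def generate_utterance_audio(
    item: str,
    task: str,
    fs_hz: int = 22400,
    seed: int | np.random.Generator = 0,
    duration_s: float = 0.8,
    f0_hz: float = 120.0,
    bandwidth_hz: float = 80.0,
) -> np.ndarray:
    """Vowel-like waveform from an all-pole (two-resonator) vocal tract.

    Voiced utterances excite the filter with a periodic impulse train at
    ``f0_hz`` and are louder; whispered utterances use a white-noise source
    at lower amplitude.  Duration fits inside the 0.9 s silent gap.
    """
    f1, f2 = utterance_formants(item, task)
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs_hz)
    if task == "voiced":
        src = np.zeros(n)
        period = int(round(fs_hz / f0_hz))
        src[::period] = 1.0
        amp = _VOICED_AMP
    else:
        src = rng.standard_normal(n)
        amp = _WHISPER_AMP
    x = src
    for f in (f1, f2):
        r = np.exp(-np.pi * bandwidth_hz / fs_hz)
        theta = 2 * np.pi * f / fs_hz
        a = [1.0, -2 * r * np.cos(theta), r * r]
        x = _sig.lfilter([1.0], a, x)
    # 10 ms raised-cosine edges
    edge = int(0.01 * fs_hz)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
    x[:edge] *= ramp
    x[-edge:] *= ramp[::-1]
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * amp
    return x


# --------------------------------------------------------------------------
# on-disk form

def write_dataset(ds: SyntheticDataset, out_dir, write_audio: bool = True) -> None:
    """Write the dataset in its exchange formats (NIfTI, TSV, WAV, JSON)."""
    import pathlib

    import nibabel as nib
    from scipy.io import wavfile

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(ds.gray_mask.astype(np.uint8), ds.affine), out / "gray_mask.nii.gz")
    nib.save(nib.Nifti1Image(ds.roi_labels.astype(np.int16), ds.affine), out / "roi_labels.nii.gz")
    (out / "roi_names.json").write_text(json.dumps(ds.roi_names, indent=1))

    for si, sub in enumerate(ds.subjects):
        sdir = out / f"sub-{si:02d}"
        sdir.mkdir(exist_ok=True)
        sub.trial_table.to_csv(sdir / "events.tsv", sep="\t", index=False)
        for ri, (vol, mot, phys) in enumerate(zip(sub.volumes, sub.motion, sub.physio)):
            nib.save(nib.Nifti1Image(vol, ds.affine), sdir / f"run-{ri}_bold.nii.gz")
            np.savetxt(sdir / f"run-{ri}_motion.txt", mot, fmt="%.6f")
            trig = np.zeros(phys.respiration.size)
            trig[phys.tr_triggers] = 1.0
            pd.DataFrame(
                {"respiration": phys.respiration, "chin_pressure": phys.chin_pressure, "trigger": trig}
            ).to_csv(sdir / f"run-{ri}_physio.tsv.gz", sep="\t", index=False, float_format="%.5f")
        if write_audio:
            adir = sdir / "audio"
            adir.mkdir(exist_ok=True)
            for _, row in sub.trial_table.head(4).iterrows():
                w = generate_utterance_audio(
                    row["item"], row["task"], ds.config.audio_fs_hz, seed=ds.config.seed
                )
                wavfile.write(
                    adir / f"run{row['run']}_t{row.name}_{row['task']}_{row['item']}.wav",
                    ds.config.audio_fs_hz,
                    (w * 32767).astype(np.int16),
                )

    gt = ds.ground_truth
    sidecar = {
        "effect_size": gt.effect_size,
        "resp_irf_peak_s": gt.resp_irf_peak_s,
        "feature_noise_sd": gt.feature_noise_sd,
        "feature_gain": gt.feature_gain,
        "pattern_rois": gt.pattern_rois,
        "pattern_voxels": {
            k: np.argwhere(v != 0).tolist() for k, v in gt.pattern_maps.items()
        },
        "seed_regions": {k: np.argwhere(v).tolist() for k, v in gt.seed_regions.items()},
        "coupled_regions": {k: np.argwhere(v).tolist() for k, v in gt.coupled_regions.items()},
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(ds.config).items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar))
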