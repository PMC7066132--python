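"""End-to-end pipeline: synthesize -> features -> GLM -> decoders ->
connectivity -> report, from one declarative YAML configuration.

Each stage reads only files written by earlier stages, records SHA-256
digests of its inputs and outputs in ``manifest.json``, and is skipped on
re-run when all recorded digests still match (stale or corrupted
intermediates are detected as digest mismatches, never silently reused).
Every random-number seed is derived from the single top-level seed and
logged in the manifest, so a fixed config + seed reproduces byte-identical
tables and hash-equal map arrays.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustics import extract_audio_features
from .connectivity import contrast_connectivity, group_connectivity, localize_seed, seed_correlation
from .glm import build_design, extract_trial_features, fit_glm, nuisance_residuals
from .physio import compute_resp_irf
from .rfe import RFEConfig, decode_roi, group_roi_stats, permutation_null
from .searchlight import group_searchlight, run_searchlight
from .synth import ExperimentConfig, generate_experiment, generate_utterance_audio, write_dataset

__all__ = ["default_config", "run_pipeline", "make_report", "load_config"]

STAGES = ("synth", "audio", "glm", "decode_roi", "searchlight", "connect", "report")


def default_config() -> dict:
    """Demo configuration: every analysis parameter of the emulated study
    under its own key, at a desk-scale problem size."""
    return {
        "experiment": {
            "n_subjects": 3,
            "n_runs": 2,
            "n_trials_per_run": 20,
            "grid_shape": [16, 16, 16],
            "roi_size": 3,
            "effect_size": 1.2,
            "patterns": [["lip", "bilabial-vs-alveolar"], ["larynx", "voiced-vs-whispered"]],
            "couplings": [["lip", "velum"]],
        },
        "analysis": {
            "censor_mm": 0.4,
            "epoch_s": 16.0,
            "decode_contrast": "task",      # voiced vs whispered
            "rois": ["lip", "tongue", "larynx", "velum"],
            "rfe": {
                "n_iterations": 3,
                "splits_per_elimination": 2,
                "n_nested_splits": 6,
                "elim_fraction": 0.30,
                "nested_ratio": 0.9,
                "slack_fraction": 0.05,
                "smooth_kernel": 3,
                "n_permutations": 5,
            },
            "searchlight": {"radius_mm": 7.0, "n_permutations": 0, "q": 0.05},
            "connect": {"seed_contrast": "bilabial-vs-alveolar", "threshold_p": 0.05},
            "q": 0.05,
        },
        "seed": 0,
    }


def load_config(path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path, cfg: dict):
        self.path = path
        self.data = {"version": __version__, "config_hash": _config_hash(cfg),
                     "seeds": {}, "stages": {}}
        self.previous = None
        if path.exists():
            prev = json.loads(path.read_text())
            if prev.get("config_hash") == self.data["config_hash"]:
                self.previous = prev

    def stage_cached(self, name: str, out_dir: Path) -> bool:
        if not self.previous or name not in self.previous.get("stages", {}):
            return False
        rec = self.previous["stages"][name]
        for rel, dig in {**rec["inputs"], **rec["outputs"]}.items():
            p = out_dir / rel
            if not p.exists():
                return False
            if _digest(p) != dig:
                raise RuntimeError(
                    f"stage {name}: digest mismatch for {rel} (stale or corrupted cache)"
                )
        self.data["stages"][name] = rec
        return True

    def record(self, name: str, out_dir: Path, inputs: list[Path], outputs: list[Path],
               seconds: float) -> None:
        self.data["stages"][name] = {
            "inputs": {str(p.relative_to(out_dir)): _digest(p) for p in inputs},
            "outputs": {str(p.relative_to(out_dir)): _digest(p) for p in outputs},
            "wall_s": round(seconds, 3),
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _experiment_config(cfg: dict, seed: int) -> ExperimentConfig:
    exp = dict(cfg["experiment"])
    for key in ("grid_shape",):
        if key in exp:
            exp[key] = tuple(exp[key])
    for key in ("patterns", "couplings"):
        if key in exp:
            exp[key] = tuple(tuple(x) for x in exp[key])
    exp["seed"] = seed
    return ExperimentConfig(**exp)


def run_pipeline(config: dict | str | Path, out_dir, seed: int | None = None,
                 stages: tuple[str, ...] = STAGES, log=print) -> Path:
    """Execute the pipeline stages in dependency order; returns the output
    directory (containing ``manifest.json``)."""
    cfg = load_config(config) if not isinstance(config, dict) else json.loads(json.dumps(config))
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", cfg)
    (out / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))

    seeds = np.random.SeedSequence(cfg["seed"]).generate_state(len(STAGES)) % (2**31)
    manifest.data["seeds"] = {s: int(v) for s, v in zip(STAGES, seeds)}

    state: dict = {"cfg": cfg, "out": out, "manifest": manifest}
    for name in STAGES:
        if name not in stages:
            continue
        fn = globals()[f"_stage_{name}"]
        if manifest.stage_cached(name, out):
            log(f"stage={name} status=cached")
            continue
        t0 = time.perf_counter()
        inputs, outputs = fn(state, int(manifest.data["seeds"][name]))
        dt = time.perf_counter() - t0
        manifest.record(name, out, inputs, outputs, dt)
        log(f"stage={name} status=done wall_s={dt:.2f} outputs={len(outputs)}")
    manifest.save()
    return out


# --------------------------------------------------------------------------
# stages: each returns (input paths, output paths) relative to the run dir

def _load_dataset(state):
    if "ds" not in state:
        state["ds"] = generate_experiment(
            _experiment_config(state["cfg"], state["cfg"]["seed"])
        )
    return state["ds"]


def _stage_synth(state, seed):
    out = state["out"]
    ds = _load_dataset(state)
    ddir = out / "data"
    write_dataset(ds, ddir)
    outputs = sorted(p for p in ddir.rglob("*") if p.is_file())
    return [out / "config.json"], outputs


def _stage_audio(state, seed):
    out = state["out"]
    ds = _load_dataset(state)
    cfg = ds.config
    rows = []
    for si, sub in enumerate(ds.subjects):
        for idx, tr in sub.trial_table.iterrows():
            w = generate_utterance_audio(
                tr["item"], tr["task"], cfg.audio_fs_hz, seed=seed + idx
            )
            feats = extract_audio_features(w, cfg.audio_fs_hz)
            rows.append(
                {"subject": si, "run": tr["run"], "trial": idx, "task": tr["task"],
                 "item": tr["item"], "loudness": feats.loudness,
                 "f1_hz": feats.f1_hz, "f2_hz": feats.f2_hz}
            )
    path = out / "features_audio.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")
    return [out / "config.json"], [path]


def _stage_glm(state, seed):
    out = state["out"]
    ds = _load_dataset(state)
    cfg = ds.config
    gray_cols = np.argwhere(ds.gray_mask)
    gdir = out / "glm"
    gdir.mkdir(exist_ok=True)
    outputs = []
    state["betas"] = []
    irf_rows = []
    for si, sub in enumerate(ds.subjects):
        data = np.concatenate(
            [v.reshape(-1, v.shape[-1]).T for v in sub.volumes], axis=0
        )[:, ds.gray_mask.reshape(-1)]
        design = build_design(
            sub.trial_table, np.vstack(sub.motion), cfg.n_vols_per_run,
            cfg.tr_s, cfg.drift_order,
        )
        betas, _ = fit_glm(data, design)
        resid = nuisance_residuals(data, design)
        bsm = extract_trial_features(resid, sub.trial_table, design, gray_cols)
        state["betas"].append(bsm)

        np.save(gdir / f"sub-{si:02d}_betas.npy", bsm.values.astype(np.float32))
        bsm.trial_table.to_csv(gdir / f"sub-{si:02d}_trials.tsv", sep="\t", index=False)
        np.savetxt(gdir / f"sub-{si:02d}_voxels.tsv", gray_cols, fmt="%d", delimiter="\t")
        outputs += [gdir / f"sub-{si:02d}_betas.npy", gdir / f"sub-{si:02d}_trials.tsv",
                    gdir / f"sub-{si:02d}_voxels.tsv"]

        irf = compute_resp_irf(sub.volumes, ds.gray_mask, sub.trial_table, cfg.tr_s)
        for lag, val in zip(irf.timepoints_s, irf.mean_response):
            irf_rows.append({"subject": si, "lag_s": lag, "response": val})
    path = gdir / "resp_irf.tsv"
    pd.DataFrame(irf_rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
    outputs.append(path)
    return [out / "config.json"], outputs


def _require_betas(state):
    if "betas" not in state:
        _stage_glm(state, int(state["manifest"].data["seeds"]["glm"]))
    return state["betas"]


def _stage_decode_roi(state, seed):
    out = state["out"]
    ds = _load_dataset(state)
    an = state["cfg"]["analysis"]
    rfe_cfg = RFEConfig(rng_seed=seed, **{k: v for k, v in an["rfe"].items()})
    betas = _require_betas(state)
    gray_cols = np.argwhere(ds.gray_mask)
    col_of = {tuple(c): i for i, c in enumerate(gray_cols)}
    rows = []
    for si, bsm in enumerate(betas):
        y = bsm.labels_task
        runs = bsm.runs
        for roi in an["rois"]:
            coords = np.argwhere(ds.roi_mask(roi) & ds.gray_mask)
            cols = np.asarray([col_of[tuple(c)] for c in coords])
            X = bsm.values[:, cols]
            res = decode_roi(X, y, runs, rfe_cfg, coords, ds.gray_mask.shape)
            null = permutation_null(X, y, runs, rfe_cfg, coords, ds.gray_mask.shape)
            rows.append({"subject": si, "roi": roi,
                         "final_accuracy": res.final_accuracy,
                         "chance": null.chance_level,
                         "p_perm": null.p_value(res.final_accuracy)})
    table = pd.DataFrame(rows)
    p1 = out / "roi_decoding.tsv"
    table.to_csv(p1, sep="\t", index=False, float_format="%.4f")
    outputs = [p1]
    if table["subject"].nunique() >= 3:
        group = group_roi_stats(table, state["cfg"]["analysis"]["q"])
        p2 = out / "roi_group.tsv"
        group.to_csv(p2, sep="\t", index=False, float_format="%.4g")
        outputs.append(p2)
    return [out / "config.json"], outputs


def _stage_searchlight(state, seed):
    import nibabel as nib

    out = state["out"]
    ds = _load_dataset(state)
    sl = state["cfg"]["analysis"]["searchlight"]
    betas = _require_betas(state)
    acc_maps = []
    for bsm in betas:
        smap = run_searchlight(
            bsm.values, ds.gray_mask, bsm.labels_task, bsm.runs,
            radius_mm=sl["radius_mm"], voxel_mm=ds.config.voxel_mm,
            n_permutations=sl["n_permutations"], q=sl["q"], rng_seed=seed,
        )
        acc_maps.append(smap.accuracy)
    t_map, p_map, qsig = group_searchlight(acc_maps, 0.5, sl["q"])
    sdir = out / "searchlight"
    sdir.mkdir(exist_ok=True)
    outputs = []
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_acc = np.nanmean(np.stack(acc_maps), axis=0)
    for name, arr in [("mean_accuracy", mean_acc),
                      ("group_t", t_map), ("group_p", p_map),
                      ("group_qsig", qsig.astype(np.uint8))]:
        arr = np.nan_to_num(arr, nan=0.0, posinf=1e6, neginf=-1e6)
        p = sdir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), ds.affine), p)
        outputs.append(p)
    return [out / "config.json"], outputs


def _stage_connect(state, seed):
    import nibabel as nib
    from scipy import stats as _sts

    out = state["out"]
    ds = _load_dataset(state)
    cn = state["cfg"]["analysis"]["connect"]
    betas = _require_betas(state)
    gray_cols = np.argwhere(ds.gray_mask)
    col_of = {tuple(c): i for i, c in enumerate(gray_cols)}

    from .glm import contrast_vector
    cvec = contrast_vector(cn["seed_contrast"])

    z_all, z_voiced, z_whisp, seed_rows = [], [], [], []
    for si, bsm in enumerate(betas):
        # subject-level localizer: two-sample t on beta series between the
        # positive and negative conditions of the seed contrast
        conds = (bsm.trial_table["task"] + "_" + bsm.trial_table["item"]).to_numpy()
        from .glm import CONDITIONS
        signs = np.asarray([np.sign(cvec[CONDITIONS.index(c)]) for c in conds])
        pos, neg = bsm.values[signs > 0], bsm.values[signs < 0]
        t, _ = _sts.ttest_ind(pos, neg, axis=0)
        t_map = np.zeros(ds.gray_mask.shape)
        t_map[tuple(gray_cols.T)] = np.nan_to_num(t)
        region = localize_seed(t_map, pos.shape[0] + neg.shape[0] - 2,
                               ds.gray_mask, cn["threshold_p"], name="seed")
        if region is None:
            seed_rows.append({"subject": si, "seed": "seed", "n_voxels": 0,
                              "peak": "none", "flagged": True})
            continue
        seed_rows.append({"subject": si, "seed": region.name,
                          "n_voxels": region.n_voxels,
                          "peak": ",".join(map(str, region.peak_coord)),
                          "flagged": False})
        cols = np.asarray([col_of[tuple(c)] for c in region.voxels
                           if tuple(c) in col_of])
        cm = seed_correlation(bsm.values, cols)
        z_all.append(cm.z)
        for task, store in (("voiced", z_voiced), ("whispered", z_whisp)):
            sub = bsm.labels_task == task
            store.append(seed_correlation(bsm.values, cols, sub).z)

    cdir = out / "connect"
    cdir.mkdir(exist_ok=True)
    pd.DataFrame(seed_rows).to_csv(cdir / "seed_report.tsv", sep="\t", index=False)
    outputs = [cdir / "seed_report.tsv"]
    if len(z_all) >= 3:
        t, p = group_connectivity(z_all)
        tc, pc = contrast_connectivity(z_voiced, z_whisp)
        for name, vals in [("group_t", t), ("group_p", p),
                           ("contrast_t", tc), ("contrast_p", pc)]:
            arr = np.zeros(ds.gray_mask.shape, dtype=np.float32)
            arr[tuple(gray_cols.T)] = np.nan_to_num(vals, nan=0.0, posinf=1e6, neginf=-1e6)
            path = cdir / f"{name}.nii.gz"
            nib.save(nib.Nifti1Image(arr, ds.affine), path)
            outputs.append(path)
    return [out / "config.json"], outputs


def _stage_report(state, seed):
    out = state["out"]
    inputs = [p for p in [out / "roi_decoding.tsv", out / "glm" / "resp_irf.tsv",
                          out / "features_audio.tsv"] if p.exists()]
    outputs = make_report(out)
    return inputs, outputs


def make_report(out_dir) -> list[Path]:
    """Summary tables and figures from existing stage outputs.

    All numbers are read from stage files, never recomputed, and sections
    whose stage output is missing are marked absent.  Regeneration is
    idempotent.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    rdir = out / "report"
    rdir.mkdir(exist_ok=True)
    lines = ["# Pipeline report", ""]
    outputs = []

    roi_path = out / "roi_decoding.tsv"
    if roi_path.exists():
        df = pd.read_csv(roi_path, sep="\t")
        summ = df.groupby("roi")[["final_accuracy", "chance"]].mean()
        lines += ["## ROI decoding (mean over subjects)", "",
                  summ.to_csv(sep="\t").strip(), ""]
        fig, ax = plt.subplots(figsize=(5, 3))
        x = np.arange(len(summ))
        ax.bar(x - 0.2, summ["final_accuracy"], 0.4, label="accuracy", color="tab:red")
        ax.bar(x + 0.2, summ["chance"], 0.4, label="permutation chance", color="tab:green")
        ax.set_xticks(x, summ.index, rotation=45)
        ax.set_ylabel("proportion correct")
        ax.legend()
        fig.tight_layout()
        fig.savefig(rdir / "roi_accuracy.png", dpi=100)
        plt.close(fig)
        outputs.append(rdir / "roi_accuracy.png")
    else:
        lines += ["## ROI decoding", "", "absent", ""]

    irf_path = out / "glm" / "resp_irf.tsv"
    if irf_path.exists():
        df = pd.read_csv(irf_path, sep="\t")
        mean = df.groupby("lag_s")["response"].mean()
        lines += ["## Respiratory impulse response (gray-matter average)", "",
                  mean.to_csv(sep="\t").strip(), "",
                  f"peak lag: {mean.idxmax():g} s", ""]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(mean.index, mean.values, "o-")
        ax.set_xlabel("lag from trial onset (s)")
        ax.set_ylabel("mean signal (a.u.)")
        fig.tight_layout()
        fig.savefig(rdir / "resp_irf.png", dpi=100)
        plt.close(fig)
        outputs.append(rdir / "resp_irf.png")
    else:
        lines += ["## Respiratory impulse response", "", "absent", ""]

    audio_path = out / "features_audio.tsv"
    if audio_path.exists():
        df = pd.read_csv(audio_path, sep="\t")
        summ = df.groupby("task")[["loudness", "f1_hz", "f2_hz"]].mean()
        lines += ["## Acoustic measures (mean per task)", "",
                  summ.to_csv(sep="\t").strip(), ""]
    else:
        lines += ["## Acoustic measures", "", "absent", ""]

    path = rdir / "report.md"
    path.write_text("\n".join(lines))
    return [path] + outputs
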