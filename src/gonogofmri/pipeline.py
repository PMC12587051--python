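"""End-to-end orchestration: simulate -> behavior -> fit-hrf -> glm -> roi.

Each stage logs its parameters and seed; the run emits a JSON manifest
listing every output file with its SHA-256 checksum, so identical seeds
yield byte-identical artifacts and the bookkeeping needed for longitudinal
multi-session analyses is explicit.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from gonogofmri import behavior as bh
from gonogofmri import glm as glm_mod
from gonogofmri import hrf as hrf_mod
from gonogofmri import io as io_mod
from gonogofmri import motion as motion_mod
from gonogofmri import roistats
from gonogofmri import synthgen
from gonogofmri.config import PipelineConfig

log = logging.getLogger("gonogofmri")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_stage(config: PipelineConfig, out: Path) -> dict:
    """Generate one synthetic session (behavior + BOLD) and write it out."""
    seed = int(config["seed"])
    sim = config["simulate"]
    acq = config["acquisition"]
    session_cfg = synthgen.SessionConfig(n_blocks=int(sim["n_blocks"]),
                                         seed=seed)
    recording, truth_trials = synthgen.make_session(session_cfg)
    rois = synthgen.make_roiset(grid_shape=tuple(sim["grid_shape"]),
                                voxel_size_um=tuple(acq["voxel_size_um"]))
    truth = synthgen.GroundTruth(seed=seed)
    tr = float(acq["tr"])
    n_volumes = int(np.ceil(recording.duration / tr))
    bold, motion = synthgen.make_bold(truth_trials, rois, truth, tr=tr,
                                      n_volumes=n_volumes)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_bold(bold, out / "bold.nii")
    io_mod.write_roiset(rois, out / "rois.nii")
    io_mod.write_events(truth_trials, out / "events.tsv")
    io_mod.write_motion(motion, out / "motion.tsv")
    io_mod.write_json(truth.to_dict(), out / "ground_truth.json")
    np.save(out / "lick_trace.npy", recording.lick)
    np.save(out / "sniff_trace.npy", recording.sniff)
    io_mod.write_json(
        {"sample_rate_hz": recording.sample_rate_hz,
         "valve_events": [list(v) for v in recording.valve_events],
         "odor_labels": list(recording.odor_labels),
         "water_events": list(recording.water_events)},
        out / "recording.json")
    log.info("simulate: %d trials, %d volumes, seed %d",
             len(truth_trials), n_volumes, seed)
    return {"recording": recording, "trials": truth_trials, "rois": rois,
            "truth": truth, "bold": bold, "motion": motion}


def behavior_stage(config: PipelineConfig, state: dict, out: Path) -> dict:
    """Parse the raw streams back into a trial table and censor for motion."""
    beh = config["behavior"]
    mo = config["motion"]
    rec = state["recording"]
    licks = bh.detect_licks(rec.lick, rec.sample_rate_hz,
                            threshold=beh["lick_threshold"],
                            refractory=beh["lick_refractory"])
    trials = bh.classify_trials(rec.valve_events, rec.odor_labels, licks,
                                window_start=beh["window_start"],
                                window_duration=beh["window_duration"],
                                onset_latency=beh["onset_latency"],
                                adjacency=beh["adjacency"])
    trials = bh.assign_blocks(
        trials, state["trials"]["block_id"].value_counts().iloc[0])
    fd = motion_mod.framewise_displacement(
        state["motion"], sphere_radius=mo["sphere_radius_um"])
    trials, n_censored = motion_mod.censor_trials(
        trials, fd, tr=state["bold"].tr, threshold=mo["threshold_um"],
        trial_window=mo["trial_window"])
    summary = bh.performance_curve(trials,
                                   n_stage_blocks=beh["n_stage_blocks"])
    io_mod.write_events(trials, out / "trials.tsv")
    io_mod.write_motion(state["motion"], out / "motion_fd.tsv", fd=fd)
    io_mod.write_json(
        {"block_accuracy": summary.block_accuracy.to_dict(),
         "n_censored_motion": n_censored},
        out / "behavior_summary.json")
    log.info("behavior: %d trials, %d censored for motion",
             len(trials), n_censored)
    return {**state, "trials_parsed": trials, "fd": fd, "summary": summary}


def hrf_stage(config: PipelineConfig, state: dict, out: Path) -> dict:
    """Empirical HRF from ventral-striatal Hit responses + grid fit."""
    hcfg = config["hrf"]
    trials = state["trials_parsed"]
    onsets = trials.loc[trials["outcome"] == "Hit", "stimulus_onset"]
    target = hrf_mod.extract_empirical(state["bold"], state["rois"]["VS"],
                                       onsets, length=hcfg["length"])
    params, rmse = hrf_mod.fit_grid(target, strategy=hcfg["strategy"],
                                    normalize=hcfg["normalize"])
    params.to_json(out / "hrf.json")
    io_mod.write_json({"rmse": rmse, "n_events": target.n_events},
                      out / "hrf_fit.json")
    log.info("hrf: fitted params %s, rmse %.4g", params, rmse)
    return {**state, "hrf": params, "hrf_target": target}


def glm_stage(config: PipelineConfig, state: dict, out: Path) -> dict:
    """First-level GLM with nuisance regressors and a Hit > FA t map."""
    gcfg = config["glm"]
    bold = state["bold"]
    if gcfg["smoothing_fwhm_um"] > 0:
        bold = glm_mod.smooth(bold, fwhm_um=gcfg["smoothing_fwhm_um"])
    design = glm_mod.build_design(state["trials_parsed"], state["hrf"],
                                  n_volumes=bold.n_volumes, tr=bold.tr,
                                  motion=state["motion"], bold=bold,
                                  rois=state["rois"])
    design.to_frame().to_csv(out / "design.tsv", sep="\t", index=False)
    fit = glm_mod.fit_glm(bold, design, mask=state["rois"].brain_mask())
    tmap = glm_mod.contrast_tmap(fit, {"Hit": 1.0, "FA": -1.0})
    thresholded = glm_mod.fdr_threshold(tmap, q=gcfg["q"],
                                        extent=gcfg["extent"],
                                        mask=state["rois"].brain_mask())
    io_mod.write_json(
        {"df": fit.df, "contrast": "Hit>FA",
         "n_significant": thresholded.meta["n_voxels"]},
        out / "glm_report.json")
    log.info("glm: df=%d, %d significant voxels (Hit>FA)",
             fit.df, thresholded.meta["n_voxels"])
    return {**state, "glm_fit": fit, "tmap": tmap,
            "thresholded": thresholded}


def roi_stage(config: PipelineConfig, state: dict, out: Path) -> dict:
    """FIR responses and peak amplitudes per ROI and condition."""
    trials = state["trials_parsed"]
    rows = []
    for region in ("VS", "DMS", "DLS", "HC", "MOB"):
        responses = roistats.fir_extract(
            state["bold"], state["rois"][region], trials,
            [c for c in ("Hit", "FA", "CR")
             if (trials["outcome"] == c).any()])
        for cond, resp in responses.items():
            resp.roi = region
            for k, v in enumerate(resp.values):
                rows.append(dict(roi=region, condition=cond,
                                 bin_start_s=k * resp.tr, pct=v,
                                 n_trials=resp.n_trials))
    fir = pd.DataFrame(rows)
    fir.to_csv(out / "fir.tsv", sep="\t", index=False)
    peaks = {
        f"{r}_{c}": float(
            fir.query("roi == @r and condition == @c")
            .sort_values("bin_start_s")["pct"].iloc[2])
        for r in fir["roi"].unique() for c in
        fir.loc[fir["roi"] == r, "condition"].unique()}
    io_mod.write_json(peaks, out / "roi_peaks.json")
    log.info("roi: %d FIR curves", fir[["roi", "condition"]].drop_duplicates().shape[0])
    return {**state, "fir": fir, "peaks": peaks}


STAGES = [
    ("simulate", simulate_stage),
    ("behavior", behavior_stage),
    ("fit-hrf", hrf_stage),
    ("glm", glm_stage),
    ("roi", roi_stage),
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; return the state dict plus a manifest
    of output files and checksums (also written to ``manifest.json``)."""
    out = Path(config["paths"]["out"])
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    state: dict = {}
    for name, stage in STAGES:
        try:
            if name == "simulate":
                state = stage(config, out)
            else:
                state = stage(config, state, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.is_file() and p.name != "manifest.json"}
    io_mod.write_json(manifest, out / "manifest.json")
    state["manifest"] = manifest
    return state
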