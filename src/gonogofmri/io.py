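"""Readers/writers for the standard formats the pipeline touches.

BOLD runs and masks are NIfTI-1 (voxel sizes in mm, TR in the time pixdim);
trial tables are BIDS-style ``events.tsv`` files (``onset``, ``duration``,
``trial_type``, ``response_time``) with the remaining trial-table fields
carried as namespaced extension columns; motion parameters are TSV with the
six rigid-body columns plus a derived ``fd`` column; ground truth and
statistics reports are JSON.
"""

from __future__ import annotations

import json
import logging
import warnings

import nibabel as nib
import numpy as np
import pandas as pd

from gonogofmri.core import BOLDRun, ROISet, TRIAL_COLUMNS, validate_trial_table
from gonogofmri.motion import MOTION_COLUMNS

log = logging.getLogger("gonogofmri")

#: extension columns written alongside the BIDS triplet, namespaced to
#: avoid clashing with the standard
_EXT_PREFIX = "gng_"
_EXT_COLUMNS = ["trial_id", "block_id", "session_id", "odor",
                "stimulus_onset", "first_lick_time", "outcome",
                "censor_reason"]


def write_bold(run: BOLDRun, path) -> None:
    img = nib.Nifti1Image(np.asarray(run.data), run.affine)
    zooms = tuple(v / 1000.0 for v in run.voxel_size_um) + (run.tr,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_bold(path, tr_fallback: float = 2.5) -> BOLDRun:
    """Load a 4-D NIfTI-1 BOLD run; missing TR falls back to the config
    value with a logged warning."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D BOLD file, got {data.ndim}-D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr <= 0:
        log.warning("TR missing from NIfTI header; using fallback %.3g s",
                    tr_fallback)
        warnings.warn("TR missing from header; using configured fallback")
        tr = tr_fallback
    voxel_um = tuple(1000.0 * z for z in zooms[:3])
    return BOLDRun(data=data, tr=tr, voxel_size_um=voxel_um,
                   affine=img.affine)


def write_roiset(rois: ROISet, path) -> None:
    """Write masks as a single NIfTI-1 label volume plus a JSON legend."""
    labels = np.zeros(rois.shape, dtype=np.int16)
    legend = {}
    for i, name in enumerate(rois.names, start=1):
        labels[rois[name]] = i
        legend[name] = i
    img = nib.Nifti1Image(labels, rois.affine)
    img.header.set_zooms(tuple(v / 1000.0 for v in rois.voxel_size_um))
    nib.save(img, str(path))
    with open(str(path) + ".json", "w") as fh:
        json.dump(legend, fh, indent=2)


def read_roiset(path) -> ROISet:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    with open(str(path) + ".json") as fh:
        legend = json.load(fh)
    masks = {name: labels == i for name, i in legend.items()}
    zooms = img.header.get_zooms()
    return ROISet(masks=masks,
                  voxel_size_um=tuple(1000.0 * z for z in zooms[:3]),
                  affine=img.affine)


def write_events(trials: pd.DataFrame, path, odor_duration: float = 1.0) -> None:
    """Write a trial table as a BIDS-style events TSV (lossless)."""
    validate_trial_table(trials)
    out = pd.DataFrame({
        "onset": trials["valve_open_time"],
        "duration": odor_duration,
        "trial_type": trials["outcome"],
        "response_time": trials["reaction_time"],
    })
    for c in _EXT_COLUMNS:
        out[_EXT_PREFIX + c] = trials[c]
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> pd.DataFrame:
    """Read an events TSV back into a trial table.

    Files written by :func:`write_events` round-trip losslessly; plain BIDS
    files (no extension columns) are accepted with the derivable fields
    reconstructed.  A Hit/FA row without a response time is an error.
    """
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"malformed events file: missing {col}")
    if (df["onset"] < 0).any():
        raise ValueError("negative onsets")
    ext = {c: _EXT_PREFIX + c in df.columns for c in _EXT_COLUMNS}
    trials = pd.DataFrame()
    n = len(df)
    trials["trial_id"] = (df[_EXT_PREFIX + "trial_id"] if ext["trial_id"]
                          else np.arange(n))
    trials["block_id"] = (df[_EXT_PREFIX + "block_id"] if ext["block_id"]
                          else 0)
    trials["session_id"] = (df[_EXT_PREFIX + "session_id"]
                            if ext["session_id"] else 0)
    trials["odor"] = df[_EXT_PREFIX + "odor"] if ext["odor"] else np.where(
        df["trial_type"].isin(["Hit", "Miss"]), "go", "nogo")
    trials["valve_open_time"] = df["onset"]
    trials["stimulus_onset"] = (df[_EXT_PREFIX + "stimulus_onset"]
                                if ext["stimulus_onset"]
                                else df["onset"] + 0.1)
    trials["first_lick_time"] = (df[_EXT_PREFIX + "first_lick_time"]
                                 if ext["first_lick_time"] else np.nan)
    rt = df["response_time"] if "response_time" in df.columns else np.nan
    trials["reaction_time"] = rt
    trials["outcome"] = (df[_EXT_PREFIX + "outcome"] if ext["outcome"]
                         else df["trial_type"])
    trials["censor_reason"] = (df[_EXT_PREFIX + "censor_reason"]
                               if ext["censor_reason"] else "none")
    trials = trials[TRIAL_COLUMNS].copy()
    if len(trials):
        responded = trials["outcome"].isin(["Hit", "FA"])
        if trials.loc[responded, "reaction_time"].isna().any():
            raise ValueError("Hit/FA rows must carry a response time")
        validate_trial_table(trials)
    return trials


def write_motion(motion: pd.DataFrame, path, fd: np.ndarray | None = None) -> None:
    out = motion[MOTION_COLUMNS].copy()
    if fd is not None:
        out["fd"] = fd
    out.to_csv(path, sep="\t", index=False)


def read_motion(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion TSV missing columns: {missing}")
    return df


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
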