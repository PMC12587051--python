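"""Framewise head-motion quantification and motion-based trial censoring.

Framewise displacement (FD) follows the Power-style convention: the sum of
absolute backward differences of the three translations plus the rotational
arc lengths on a sphere approximating the mouse head (radius 5 mm).  Trials
(Hit, FA, or CR) whose window overlaps any volume with FD above the voxel
diameter (200 um in-plane by default) are reassigned to the Nuisance
condition and excluded from the task contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def framewise_displacement(params: pd.DataFrame,
                           sphere_radius: float = 5000.0) -> np.ndarray:
    """Per-volume FD in micrometres: ``sum |d trans| + r * sum |d rot|``.

    Translations in um, rotations in radians; backward differences with
    ``fd[0] = 0``.
    """
    missing = [c for c in MOTION_COLUMNS if c not in params.columns]
    if missing:
        raise ValueError(f"motion table missing columns: {missing}")
    vals = params[MOTION_COLUMNS].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite motion parameters")
    if len(vals) < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    d = np.abs(np.diff(vals, axis=0))
    fd = d[:, :3].sum(axis=1) + sphere_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def censor_trials(trials: pd.DataFrame, fd: np.ndarray, tr: float,
                  threshold: float = 200.0,
                  trial_window: float = 2.2) -> tuple:
    """Reassign motion-contaminated scoreable trials to Nuisance.

    A Hit/FA/CR trial is censored when the interval
    ``[valve_open, valve_open + trial_window]`` (valve opening through the
    response-window end) overlaps any volume whose FD exceeds ``threshold``
    (um; the in-plane voxel diameter by default).  The maximum FD over the
    overlapped volumes is the per-trial statistic, so the rule is the
    stricter max-FD variant.  Returns ``(trial table, n_reassigned)``;
    censoring is idempotent and never rescinds a Nuisance label.
    """
    fd = np.asarray(fd, dtype=float)
    out = trials.copy()
    if fd.size == 0:
        warnings.warn("empty FD series; no censoring applied")
        return out, 0
    bad_volumes = np.flatnonzero(fd > threshold)
    if bad_volumes.size == 0:
        return out, 0
    n_re = 0
    for idx, row in out.iterrows():
        if row["outcome"] not in ("Hit", "FA", "CR"):
            continue
        start = row["valve_open_time"]
        end = start + trial_window
        # volumes whose acquisition interval [v*tr, (v+1)*tr) intersects
        # the trial window
        v0 = int(np.floor(start / tr))
        v1 = int(np.floor(end / tr))
        overlap = bad_volumes[(bad_volumes >= v0) & (bad_volumes <= v1)]
        if overlap.size:
            out.at[idx, "outcome"] = "Nuisance"
            out.at[idx, "censor_reason"] = "motion"
            out.at[idx, "reaction_time"] = np.nan
            n_re += 1
    return out, n_re
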