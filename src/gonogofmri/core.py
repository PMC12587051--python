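"""Shared containers: BOLD runs, ROI mask sets, and the trial-table schema.

The trial table is a plain :class:`pandas.DataFrame` with a fixed column
contract (``TRIAL_COLUMNS``) rather than a bespoke class, following the
convention of BIDS-style events tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Trial outcome labels. ``Nuisance`` pools everything excluded from the
#: three scoreable task conditions at the GLM level (Misses are kept as a
#: distinct outcome here and pooled downstream).
OUTCOMES = ("Hit", "Miss", "FA", "CR", "Nuisance")

CENSOR_REASONS = ("none", "adjacent_lick", "motion", "manual_reward", "random_lick")

#: Column contract for trial tables (one row per trial, times in seconds).
TRIAL_COLUMNS = [
    "trial_id",
    "block_id",
    "session_id",
    "odor",           # "go" | "nogo"
    "valve_open_time",
    "stimulus_onset",  # valve_open_time + odor-onset latency
    "first_lick_time",  # NaN if no lick
    "reaction_time",    # NaN unless outcome in {Hit, FA}
    "outcome",
    "censor_reason",
]


def empty_trial_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        TRIAL_COLUMNS,
        ["int64", "int64", "int64", "object", "float64", "float64",
         "float64", "float64", "object", "object"],
    )})


def validate_trial_table(trials: pd.DataFrame) -> None:
    """Check the trial-table invariants; raise ``ValueError`` on violation."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = set(trials["outcome"]) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcome labels: {bad}")
    has_rt = trials["reaction_time"].notna()
    responded = trials["outcome"].isin(["Hit", "FA"])
    if (has_rt != responded).any():
        raise ValueError("reaction_time must be present iff outcome is Hit or FA")
    if (trials.loc[has_rt, "reaction_time"] <= 0).any():
        raise ValueError("reaction times must be positive")
    t = trials["valve_open_time"].to_numpy()
    if len(t) > 1 and not (np.diff(t) > 0).all():
        raise ValueError("valve open times must be strictly increasing")


def default_affine(voxel_size_um) -> np.ndarray:
    """RAS affine with voxel sizes in mm (NIfTI convention), origin at 0."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = (v / 1000.0 for v in voxel_size_um)
    return aff


@dataclass
class BOLDRun:
    """A 4-D BOLD acquisition.

    Parameters
    ----------
    data
        Array of shape ``(x, y, z, t)``, arbitrary signal units.
    tr
        Repetition time in seconds (study default 2.5 s).
    voxel_size_um
        Voxel edge lengths in micrometres (study default 200 x 200 x 300).
    affine
        4x4 voxel-to-world affine in mm; derived from ``voxel_size_um`` if
        omitted.
    """

    data: np.ndarray
    tr: float = 2.5
    voxel_size_um: tuple = (200.0, 200.0, 300.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_um)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr


@dataclass
class ROISet:
    """Named boolean masks on a common grid.

    ``CSF`` and ``background`` are reserved names used for nuisance-signal
    extraction; the whole-brain mask is the union of every mask that is
    neither of those.
    """

    masks: dict = field(default_factory=dict)
    voxel_size_um: tuple = (200.0, 200.0, 300.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"ROI masks on inconsistent grids: {shapes}")
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_um)

    @property
    def shape(self) -> tuple:
        return next(iter(self.masks.values())).shape

    @property
    def names(self) -> list:
        return list(self.masks)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def brain_mask(self) -> np.ndarray:
        """Union of all tissue masks (everything except CSF and background)."""
        out = np.zeros(self.shape, dtype=bool)
        for name, m in self.masks.items():
            if name not in ("CSF", "background"):
                out |= m
        return out

    def check_disjoint(self) -> None:
        total = np.zeros(self.shape, dtype=np.int64)
        for m in self.masks.values():
            total += m.astype(np.int64)
        if (total > 1).any():
            raise ValueError("ROI masks overlap")


def roi_mean_timeseries(bold: BOLDRun, mask: np.ndarray) -> np.ndarray:
    """Mean time series over a boolean mask, shape ``(n_volumes,)``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.shape:
        raise ValueError("mask grid does not match BOLD grid")
    if not mask.any():
        raise ValueError("empty mask")
    return bold.data[mask].mean(axis=0)
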