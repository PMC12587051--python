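"""Voxelwise GLM: design assembly, OLS fitting, contrasts, FDR, conjunction.

The first-level design carries four task conditions — Hit, CR, FA, and a
pooled Nuisance condition (Misses, random licks, manual rewards, and
censored trials) — as stick functions at stimulus onsets convolved with the
behaving-mouse HRF at microtime resolution and sampled at the TR grid.
Nuisance columns are the six rigid-body motion parameters, the ventricular
(CSF) and whole-brain mean signals with their backward-difference
derivatives, and one intercept per concatenated block.

Inference: voxelwise t maps, second-level one-sample t across subjects,
Benjamini–Hochberg FDR thresholding over in-mask voxels with a cluster
extent filter (6-connectivity), and voxelwise conjunction of binary maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from gonogofmri.core import BOLDRun, ROISet, roi_mean_timeseries
from gonogofmri.hrf import HRFParams, double_gamma, DT_MICRO
from gonogofmri.motion import MOTION_COLUMNS

TASK_CONDITIONS = ("Hit", "CR", "FA", "Nuisance4")

#: Sentinel for infinite t at zero within-group variance.
T_CAP = 1e6


def pooled_condition(outcome: str) -> str:
    """Map trial outcomes to GLM conditions (Miss and censored trials pool
    into the fourth condition)."""
    return outcome if outcome in ("Hit", "CR", "FA") else "Nuisance4"


@dataclass
class DesignMatrix:
    """Time x regressor matrix with labeled columns."""

    matrix: np.ndarray
    names: list
    tr: float
    zero_task_columns: list = field(default_factory=list)

    def __post_init__(self):
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column label count mismatch")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


@dataclass
class StatMap:
    """Voxelwise statistic volume with df and thresholding metadata."""

    data: np.ndarray
    df: float
    contrast: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def build_design(trials: pd.DataFrame, hrf: HRFParams, n_volumes: int,
                 tr: float = 2.5, motion: pd.DataFrame | None = None,
                 bold: BOLDRun | None = None, rois: ROISet | None = None,
                 block_bounds=None, dt: float = DT_MICRO) -> DesignMatrix:
    """Assemble the first-level design matrix.

    ``block_bounds`` is a list of ``(start_volume, end_volume)`` pairs for
    concatenated blocks (default: a single block spanning the run), each
    contributing an intercept column.  CSF/global columns require ``bold``
    and ``rois`` with ``CSF`` and tissue masks.
    """
    step = int(round(tr / dt))
    n_fine = n_volumes * step
    kernel = double_gamma(hrf, dt=dt)
    cols, names = [], []
    zero_cols = []
    for cond in TASK_CONDITIONS:
        onsets = trials.loc[
            trials["outcome"].map(pooled_condition) == cond, "stimulus_onset"]
        sticks = np.zeros(n_fine)
        for onset in onsets:
            i = int(round(onset / dt))
            if not 0 <= i < n_fine:
                raise ValueError(f"trial onset {onset:.2f}s outside the run")
            sticks[i] = 1.0
        reg = np.convolve(sticks, kernel)[:n_fine][::step]
        if not reg.any():
            zero_cols.append(cond)
            warnings.warn(f"condition {cond} has no events; column is all "
                          "zero and excluded from estimable contrasts")
        cols.append(reg)
        names.append(cond)
    if motion is not None:
        for c in MOTION_COLUMNS:
            cols.append(motion[c].to_numpy(dtype=float))
            names.append(c)
    if bold is not None and rois is not None:
        csf = roi_mean_timeseries(bold, rois["CSF"])
        glob = roi_mean_timeseries(bold, rois.brain_mask())
        for name, sig in (("csf", csf), ("global", glob)):
            cols.append(sig)
            names.append(name)
            deriv = np.concatenate([[0.0], np.diff(sig)])
            cols.append(deriv)
            names.append(f"{name}_deriv")
    if block_bounds is None:
        block_bounds = [(0, n_volumes)]
    for bi, (s, e) in enumerate(block_bounds):
        ic = np.zeros(n_volumes)
        ic[s:e] = 1.0
        cols.append(ic)
        names.append(f"intercept_b{bi}")
    X = np.column_stack(cols)
    keep = [i for i, n in enumerate(names) if n not in zero_cols]
    if np.linalg.matrix_rank(X[:, keep]) < len(keep):
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(matrix=X, names=names, tr=tr,
                        zero_task_columns=zero_cols)


def smooth(bold: BOLDRun, fwhm_um: float = 600.0) -> BOLDRun:
    """Per-volume 3-D Gaussian smoothing with an isotropic FWHM in um,
    converted to per-axis sigmas in (anisotropic) voxel units."""
    if fwhm_um < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_um == 0:
        return BOLDRun(data=bold.data.copy(), tr=bold.tr,
                       voxel_size_um=bold.voxel_size_um, affine=bold.affine)
    sigmas = [fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
              for v in bold.voxel_size_um]
    out = np.empty_like(bold.data, dtype=float)
    for t in range(bold.n_volumes):
        out[..., t] = ndimage.gaussian_filter(
            bold.data[..., t].astype(float), sigma=sigmas, mode="nearest")
    return BOLDRun(data=out, tr=bold.tr, voxel_size_um=bold.voxel_size_um,
                   affine=bold.affine)


@dataclass
class GLMResult:
    """OLS fit: beta volumes, residual variance, df, and the design."""

    betas: np.ndarray         # (x, y, z, n_regressors)
    resid_var: np.ndarray     # (x, y, z)
    df: int
    design: DesignMatrix
    mask: np.ndarray          # (x, y, z) bool
    xtx_inv: np.ndarray

    def beta_volume(self, name: str) -> np.ndarray:
        return self.betas[..., self.design.names.index(name)]


def fit_glm(bold: BOLDRun, design: DesignMatrix,
            mask: np.ndarray | None = None) -> GLMResult:
    """Voxelwise ordinary least squares; ``df = n_volumes - rank``.

    All-zero task columns are retained at beta 0 (pinv handles the null
    column) but flagged in the design for contrast checking.
    """
    X = design.matrix
    n, p = X.shape
    if design.n_volumes != bold.n_volumes:
        raise ValueError("design length does not match run length")
    rank = np.linalg.matrix_rank(X)
    if p - len(design.zero_task_columns) > n:
        raise ValueError("more regressors than volumes")
    if mask is None:
        mask = np.ones(bold.shape, dtype=bool)
    Y = bold.data[mask].T                      # (n_volumes, n_voxels)
    pinv = np.linalg.pinv(X)
    B = pinv @ Y                               # (p, n_voxels)
    resid = Y - X @ B
    df = n - rank
    rv = (resid ** 2).sum(axis=0) / df
    betas = np.zeros(bold.shape + (p,))
    betas[mask] = B.T
    resid_var = np.zeros(bold.shape)
    resid_var[mask] = rv
    xtx_inv = np.linalg.pinv(X.T @ X)
    return GLMResult(betas=betas, resid_var=resid_var, df=df, design=design,
                     mask=mask, xtx_inv=xtx_inv)


def _full_contrast(design: DesignMatrix, c) -> np.ndarray:
    """Expand a task-condition contrast (dict or vector over the four task
    columns) to the full regressor length."""
    full = np.zeros(len(design.names))
    if isinstance(c, dict):
        for name, w in c.items():
            if name not in design.names:
                raise ValueError(f"unknown regressor {name}")
            if w != 0 and name in design.zero_task_columns:
                raise ValueError(f"contrast touches empty condition {name}")
            full[design.names.index(name)] = w
    else:
        c = np.asarray(c, dtype=float)
        if c.shape[0] != len(TASK_CONDITIONS):
            raise ValueError("contrast vector must span the task conditions")
        for cond, w in zip(TASK_CONDITIONS, c):
            if w != 0 and cond in design.zero_task_columns:
                raise ValueError(f"contrast touches empty condition {cond}")
            full[design.names.index(cond)] = w
    if not full.any():
        raise ValueError("all-zero contrast")
    return full


def contrast_tmap(fit: GLMResult, c) -> StatMap:
    """Voxelwise ``t = c'beta / SE(c'beta)`` for a task contrast."""
    full = _full_contrast(fit.design, c)
    eff = fit.betas @ full
    var_scale = float(full @ fit.xtx_inv @ full)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / np.sqrt(fit.resid_var * var_scale)
    # noiseless voxels: zero residual variance with a real effect -> capped
    # sentinel preserving the effect sign
    degenerate = (fit.resid_var == 0) & (eff != 0)
    t[degenerate] = np.sign(eff[degenerate]) * T_CAP
    t = np.where(np.isfinite(t), t, 0.0)
    t = np.clip(t, -T_CAP, T_CAP)  # numerically-noiseless voxels
    t[~fit.mask] = 0.0
    return StatMap(data=t, df=fit.df, contrast=full)


def second_level(contrast_volumes, mask: np.ndarray | None = None) -> StatMap:
    """One-sample t across subjects, voxelwise; ``df = n - 1``.

    Voxels with zero within-group variance and a nonzero mean are reported
    at the capped sentinel ``+-T_CAP`` and flagged in ``meta``.
    """
    vols = [np.asarray(v, dtype=float) for v in contrast_volumes]
    if len(vols) < 2:
        raise ValueError("second level requires at least 2 subjects")
    shapes = {v.shape for v in vols}
    if len(shapes) > 1:
        raise ValueError(f"subject grids mismatch: {shapes}")
    Y = np.stack(vols)
    n = len(vols)
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = (sd == 0) & (mean != 0)
    t[degenerate] = np.sign(mean[degenerate]) * T_CAP
    t[(sd == 0) & (mean == 0)] = 0.0
    if mask is not None:
        t = np.where(mask, t, 0.0)
    return StatMap(data=t, df=n - 1,
                   meta={"n_degenerate": int(degenerate.sum())})


def fdr_threshold(statmap: StatMap, q: float = 0.05, extent: int = 5,
                  mask: np.ndarray | None = None) -> StatMap:
    """Benjamini–Hochberg FDR at level ``q`` over in-mask voxels (two-sided
    p from t and df), then removal of face-adjacent (6-connected) clusters
    smaller than ``extent`` voxels.  Returns a binary StatMap with
    surviving-voxel metadata."""
    t = statmap.data
    if mask is None:
        mask = np.ones(t.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    pvals = 2.0 * stats.t.sf(np.abs(t[mask]), statmap.df)
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    binary = np.zeros(t.shape, dtype=bool)
    binary[mask] = reject
    if extent > 1 and binary.any():
        structure = ndimage.generate_binary_structure(3, 1)
        labels, n_lab = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < extent)
        binary[np.isin(labels, small[small > 0])] = False
    return StatMap(data=binary, df=statmap.df, contrast=statmap.contrast,
                   meta={"q": q, "extent": extent,
                         "n_voxels": int(binary.sum())})


def conjunction(map_a: StatMap, map_b: StatMap) -> StatMap:
    """Voxelwise AND of two binary maps on the same grid: voxels
    significant in both contrasts."""
    a = np.asarray(map_a.data, dtype=bool)
    b = np.asarray(map_b.data, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("grid mismatch")
    both = a & b
    return StatMap(data=both, df=min(map_a.df, map_b.df),
                   meta={"n_voxels": int(both.sum())})
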