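"""FIR ROI responses and the statistical battery of the ROI analyses.

The finite-impulse-response (FIR) model estimates the condition response
shape without assuming an HRF: one delta regressor per post-onset TR bin
per condition (12 bins of 2.5 s cover the 30-s kernel), fitted jointly on
the ROI-mean time series and scaled to percent signal change.  The peak
amplitude convention is the value at the third post-onset time bin
(5.0–7.5 s after onset at TR 2.5 s).

Statistics: two-tailed paired/one-sample t with Cohen's d = t/sqrt(n),
repeated-measures ANOVA with Huynh–Feldt sphericity correction and eta
squared, Spearman rank correlation (permutation p at small n), and
Bonferroni alpha adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gonogofmri.core import BOLDRun, roi_mean_timeseries
from gonogofmri.glm import pooled_condition


@dataclass
class FIRResponse:
    """Per-bin percent-signal-change estimates for one ROI x condition."""

    roi: str
    condition: str
    values: np.ndarray
    tr: float
    n_trials: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class StatsResult:
    """One statistical comparison: statistic, df, p, effect size."""

    statistic: float
    df: object                     # scalar, or (df1, df2) for F
    p: float
    effect_size: float | None = None    # Cohen's d, or classical eta^2
    effect_size_partial: float | None = None
    epsilon_hf: float | None = None
    rho: float | None = None
    note: str = ""


def fir_extract(bold: BOLDRun, mask: np.ndarray, trials: pd.DataFrame,
                condition, n_bins: int = 12,
                block_bounds=None) -> dict | FIRResponse:
    """FIR estimates for one or more conditions on an ROI-mean time series.

    The ROI series is converted per block to percent signal change about
    the block mean before concatenation; delta regressors for every
    condition present in the trial table are then fitted jointly (a single
    OLS), so overlapping responses are disentangled by the model rather
    than by averaging.  Requesting a condition with zero trials is an
    error.  Returns a single :class:`FIRResponse` for a string
    ``condition`` or a dict for a list.
    """
    single = isinstance(condition, str)
    wanted = [condition] if single else list(condition)
    tr = bold.tr
    y_raw = roi_mean_timeseries(bold, mask)
    n_vol = len(y_raw)
    if block_bounds is None:
        block_bounds = [(0, n_vol)]
    y = np.empty(n_vol)
    for s, e in block_bounds:
        m = y_raw[s:e].mean()
        if m == 0:
            raise ValueError("zero-mean block signal")
        y[s:e] = 100.0 * (y_raw[s:e] / m - 1.0)

    conds = trials["outcome"].map(pooled_condition)
    present = [c for c in ("Hit", "CR", "FA", "Nuisance4")
               if (conds == c).any()]
    for w in wanted:
        if w not in present:
            raise ValueError(f"no trials for condition {w!r}")
    cols, names = [], []
    counts = {}
    for cond in present:
        onsets = trials.loc[conds == cond, "stimulus_onset"].to_numpy()
        counts[cond] = len(onsets)
        for k in range(n_bins):
            reg = np.zeros(n_vol)
            for onset in onsets:
                i = int(np.floor(onset / tr)) + k
                if i < n_vol:
                    reg[i] += 1.0
            cols.append(reg)
            names.append((cond, k))
    for bi, (s, e) in enumerate(block_bounds):
        ic = np.zeros(n_vol)
        ic[s:e] = 1.0
        cols.append(ic)
        names.append(("intercept", bi))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("collinear FIR design (event overlap beyond model "
                         "capacity)")
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    out = {}
    for cond in wanted:
        idx = [i for i, (c, _) in enumerate(names) if c == cond]
        out[cond] = FIRResponse(roi="", condition=cond, values=beta[idx],
                                tr=tr, n_trials=counts[cond])
    return out[condition] if single else out


def peak_amplitude(resp: FIRResponse) -> float:
    """Response amplitude: percent signal change at the third post-onset
    time bin (5.0–7.5 s after onset at TR 2.5 s)."""
    if len(resp.values) < 3:
        raise ValueError("need at least 3 FIR bins for the peak convention")
    return float(resp.values[2])


def _t_to_result(t: float, n: int, note: str = "") -> StatsResult:
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    d = t / math.sqrt(n) if np.isfinite(t) else np.inf
    return StatsResult(statistic=t, df=df, p=p, effect_size=d, note=note)


def paired_t(a, b) -> StatsResult:
    """Two-tailed paired Student's t with Cohen's d = t / sqrt(n).

    Zero-variance differences: all-zero differences give t = 0 (and d = 0);
    a constant nonzero difference gives the signed infinite sentinel.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return StatsResult(statistic=0.0, df=n - 1, p=1.0,
                               effect_size=0.0)
        return _t_to_result(math.copysign(math.inf, mean), n,
                            note="zero-variance differences")
    t = mean / (sd / math.sqrt(n))
    return _t_to_result(t, n)


def one_sample_t(a, popmean: float = 0.0) -> StatsResult:
    """Two-tailed one-sample t against ``popmean``; d = t / sqrt(n)."""
    a = np.asarray(a, dtype=float)
    return paired_t(a, np.full(a.shape, popmean))


def _epsilon_hf(data: np.ndarray, contrast: np.ndarray) -> float:
    """Huynh–Feldt epsilon for the effect spanned by the orthonormal
    contrast matrix ``contrast`` (columns), from subjects x cells data."""
    n = data.shape[0]
    d = contrast.shape[1]
    if d == 1:
        return 1.0
    scores = data @ contrast                    # (n, d)
    S = np.cov(scores, rowvar=False)
    tr_s = np.trace(S)
    gg = tr_s ** 2 / (d * np.sum(S * S))
    hf = (n * d * gg - 2.0) / (d * (n - 1.0 - d * gg))
    return float(min(1.0, hf))


def _orthonormal_contrast(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def _rm_effect(data2d: np.ndarray, contrast: np.ndarray,
               ss_total: float) -> StatsResult:
    """Within-subject effect F test from subjects x cells data and an
    orthonormal contrast spanning the effect space."""
    n = data2d.shape[0]
    scores = data2d @ contrast                 # (n, d)
    d = scores.shape[1]
    mean = scores.mean(axis=0)
    ss_effect = n * float(mean @ mean)
    centered = scores - mean
    ss_error = float((centered ** 2).sum())
    df1, df2 = d, d * (n - 1)
    if ss_error == 0:
        raise ValueError("zero error variance in RM-ANOVA")
    F = (ss_effect / df1) / (ss_error / df2)
    eps = _epsilon_hf(data2d, contrast)
    p = float(stats.f.sf(F, eps * df1, eps * df2))
    return StatsResult(
        statistic=F, df=(df1, df2), p=p,
        effect_size=ss_effect / ss_total,
        effect_size_partial=ss_effect / (ss_effect + ss_error),
        epsilon_hf=eps)


def rm_anova_hf(data) -> StatsResult | dict:
    """Repeated-measures ANOVA with Huynh–Feldt sphericity correction.

    ``data`` is subjects x conditions for a single within-subject factor
    (returns one :class:`StatsResult`), or subjects x levels_A x levels_B
    for two within factors (returns ``{'A', 'B', 'AxB'}``).  Effect sizes:
    classical eta^2 = SS_effect / SS_total (``effect_size``) and partial
    eta^2 (``effect_size_partial``).  The epsilon-corrected p uses
    F(eps*df1, eps*df2); eps is exactly 1 for 2-level effects, where
    sphericity trivially holds.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        n, k = data.shape
        if n < 2 or k < 2:
            raise ValueError("need >= 2 subjects and >= 2 conditions")
        ss_total = float(((data - data.mean()) ** 2).sum())
        return _rm_effect(data, _orthonormal_contrast(k), ss_total)
    if data.ndim == 3:
        n, a, b = data.shape
        if n < 2 or a < 2 or b < 2:
            raise ValueError("need >= 2 subjects and >= 2 levels per factor")
        flat = data.reshape(n, a * b)
        ss_total = float(((flat - flat.mean()) ** 2).sum())
        ca, cb = _orthonormal_contrast(a), _orthonormal_contrast(b)
        one_a = np.full((a, 1), 1.0 / np.sqrt(a))
        one_b = np.full((b, 1), 1.0 / np.sqrt(b))
        effects = {
            "A": np.kron(ca, one_b),
            "B": np.kron(one_a, cb),
            "AxB": np.kron(ca, cb),
        }
        # each kron product keeps the contrast columns orthonormal on the
        # a*b cells
        return {name: _rm_effect(flat, C, ss_total)
                for name, C in effects.items()}
    raise ValueError("data must be 2-D (one factor) or 3-D (two factors)")


def spearman(x, y, n_exact: int = 10, n_perm: int = 20000,
             perm_seed: int = 0) -> StatsResult:
    """Spearman rank correlation with average ranks for ties.

    For ``n <= n_exact`` the p-value is computed by permutation —
    exhaustively when n! is small (n <= 7), otherwise from a seeded random
    permutation null — rather than the large-sample approximation.
    Constant input yields the undefined-rho sentinel (NaN) with a note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatsResult(statistic=np.nan, df=len(x) - 2, p=np.nan,
                           rho=np.nan, note="constant input; rho undefined")
    n = len(x)
    rho, p_asym = stats.spearmanr(x, y)
    if n <= n_exact:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)

        def stat(perm_ry):
            return abs(np.corrcoef(rx, perm_ry)[0, 1])

        observed = stat(ry)
        if n <= 7:
            perms = itertools.permutations(ry)
            count = total = 0
            for pr in perms:
                total += 1
                if stat(np.asarray(pr)) >= observed - 1e-12:
                    count += 1
            p = count / total
        else:
            rng = np.random.default_rng(perm_seed)
            hits = 1
            for _ in range(n_perm):
                if stat(rng.permutation(ry)) >= observed - 1e-12:
                    hits += 1
            p = hits / (n_perm + 1)
    else:
        p = p_asym
    return StatsResult(statistic=rho, df=n - 2, p=float(p), rho=float(rho))


def bonferroni(alpha: float, m: int) -> float:
    """Per-test alpha level ``alpha / m``, reported at 4 decimals for audit
    logs (0.05/9 -> 0.0056; 0.05/3 -> 0.0167)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(alpha / m, 4)
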