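"""Behaving-mouse hemodynamic response function: model, extraction, fitting.

The HRF is a double-gamma kernel in the canonical SPM parameterization:
seven parameters ``p1..p7`` — response delay, undershoot delay, response
dispersion, undershoot dispersion, response:undershoot ratio, onset shift,
and kernel length.  The behaving-mouse values (p1=3 s, p2=4.8 s, p3=1.4,
p4=0.6, p5=2, p6=0, p7=30 s) are the package defaults.

Fitting proceeds the way the empirical estimation was designed: extract an
event-locked average response from a robustly responding region (ventral
striatum, Hit trials), then scan each parameter over a fixed grid and keep
the values minimizing the RMSE between the peak-normalized model (sampled
at the acquisition TR) and the peak-normalized target.  A separate
one-dimensional scan over the onset shift ``p6`` accommodates the
temporally offset olfactory-bulb response (best shift 2 s in the study's
data).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict, replace as _dc_replace

import numpy as np
from scipy.stats import gamma as _gamma

from gonogofmri.core import BOLDRun, roi_mean_timeseries

#: Microtime resolution (s) for kernel construction before TR sampling.
DT_MICRO = 0.1


@dataclass(frozen=True)
class HRFParams:
    """Seven-parameter double-gamma HRF description.

    All delays/dispersions in seconds except the unitless ratio ``p5``.
    """

    p1: float = 3.0    # response delay
    p2: float = 4.8    # undershoot delay
    p3: float = 1.4    # response dispersion
    p4: float = 0.6    # undershoot dispersion
    p5: float = 2.0    # response : undershoot ratio
    p6: float = 0.0    # onset shift
    p7: float = 30.0   # kernel length

    def __post_init__(self):
        for name in ("p1", "p2", "p3", "p4", "p5", "p7"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.p7 < self.p2:
            raise ValueError("kernel length p7 must cover the undershoot delay p2")

    def replace(self, **kw) -> "HRFParams":
        return _dc_replace(self, **kw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HRFParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def _grid(start: float, step: float, stop: float) -> np.ndarray:
    """Inclusive MATLAB-style ``start:step:stop`` grid, rounded to avoid
    floating-point drift in the grid values themselves."""
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


@dataclass
class ScanRanges:
    """Per-parameter grids for the RMSE scan (p6 and p7 held fixed)."""

    p1: np.ndarray = field(default_factory=lambda: _grid(1.0, 0.1, 6.0))
    p2: np.ndarray = field(default_factory=lambda: _grid(1.0, 0.1, 16.0))
    p3: np.ndarray = field(default_factory=lambda: _grid(0.5, 0.1, 1.5))
    p4: np.ndarray = field(default_factory=lambda: _grid(0.5, 0.1, 1.5))
    p5: np.ndarray = field(default_factory=lambda: _grid(2.0, 1.0, 20.0))
    p6: float = 0.0
    p7: float = 30.0

    def __post_init__(self):
        for name in ("p1", "p2", "p3", "p4", "p5"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.size == 0:
                raise ValueError(f"empty grid for {name}")
            if g.size > 1 and not (np.diff(g) > 0).all():
                raise ValueError(f"grid for {name} must be strictly increasing")
            object.__setattr__(self, name, g)

    @classmethod
    def fixed_except(cls, scan: str, at: HRFParams = HRFParams(), **kw) -> "ScanRanges":
        """Ranges scanning a single parameter, all others pinned to ``at``.

        Used for one-dimensional scans such as the p1-only and p2-only
        parameter-recovery checks.
        """
        fields = {}
        for name in ("p1", "p2", "p3", "p4", "p5"):
            if name == scan:
                fields[name] = kw.get(scan, getattr(cls(), name))
            else:
                fields[name] = np.array([getattr(at, name)])
        return cls(**fields, p6=at.p6, p7=at.p7)


@dataclass
class EmpiricalResponse:
    """Event-locked average response: percent signal change per post-onset
    TR bin."""

    values: np.ndarray
    tr: float
    n_events: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("empirical response contains non-finite values")


def double_gamma(params: HRFParams, dt: float = DT_MICRO,
                 duration: float | None = None) -> np.ndarray:
    """Sample the double-gamma kernel on ``t = 0, dt, 2*dt, ...``.

    ``h(t) = g(t - p6; k=p1/p3, theta=p3) - g(t - p6; k=p2/p4, theta=p4)/p5``
    with ``g`` the gamma probability density; zero before the onset shift;
    rescaled so the maximum equals 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    duration = params.p7 if duration is None else duration
    if duration < dt:
        raise ValueError("duration must be at least dt")
    t = np.arange(int(round(duration / dt))) * dt
    ts = t - params.p6
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (_gamma.pdf(ts, a=params.p1 / params.p3, scale=params.p3)
             - _gamma.pdf(ts, a=params.p2 / params.p4, scale=params.p4) / params.p5)
    h[ts < 0] = 0.0
    h = np.nan_to_num(h)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate kernel: non-positive peak")
    return h / peak


def sample_at_tr(params: HRFParams, tr: float, duration: float | None = None,
                 dt: float = DT_MICRO) -> np.ndarray:
    """Kernel point-sampled at TR-bin starts (0, TR, 2*TR, ...)."""
    duration = params.p7 if duration is None else duration
    step = int(round(tr / dt))
    if abs(step * dt - tr) > 1e-9:
        raise ValueError("TR must be an integer multiple of the microtime dt")
    fine = double_gamma(params, dt=dt, duration=duration)
    n_bins = int(np.ceil(duration / tr))
    return fine[::step][:n_bins]


def _peak_normalize(v: np.ndarray) -> np.ndarray:
    peak = np.max(v)
    if peak <= 0:
        raise ValueError("cannot peak-normalize a non-positive response")
    return v / peak


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def extract_empirical(bold: BOLDRun, mask: np.ndarray, onsets,
                      tr: float | None = None, length: float = 30.0,
                      n_baseline: int = 2) -> EmpiricalResponse:
    """Event-locked average ROI response in percent signal change.

    For each onset the ROI-mean signal over the next ``ceil(length/tr)``
    volumes is converted to % change against the mean of the ``n_baseline``
    pre-onset volumes, then averaged across onsets.  Onsets too close to the
    run boundaries are skipped with a warning; zero usable onsets is an
    error.
    """
    tr = bold.tr if tr is None else tr
    sig = roi_mean_timeseries(bold, mask)
    n_bins = int(np.ceil(length / tr))
    segs = []
    for onset in np.atleast_1d(np.asarray(onsets, dtype=float)):
        idx = int(round(onset / tr))
        if idx < n_baseline or idx + n_bins > len(sig):
            warnings.warn(f"onset {onset:.2f}s too close to run boundary; skipped")
            continue
        base = sig[idx - n_baseline:idx].mean()
        if base == 0:
            raise ValueError("zero baseline signal")
        segs.append(100.0 * (sig[idx:idx + n_bins] / base - 1.0))
    if not segs:
        raise ValueError("no usable onsets for empirical response extraction")
    return EmpiricalResponse(values=np.mean(segs, axis=0), tr=tr, n_events=len(segs))


def _target_values(target) -> tuple:
    if isinstance(target, EmpiricalResponse):
        return target.values, target.tr
    raise TypeError("target must be an EmpiricalResponse")


def fit_grid(target: EmpiricalResponse, ranges: ScanRanges | None = None,
             strategy: str = "coordinate", normalize: bool = True,
             max_sweeps: int = 10) -> tuple:
    """Grid scan for the HRF parameters minimizing RMSE to a target response.

    Both the model (sampled at the target's TR) and the target are
    peak-normalized before the RMSE is computed (``normalize=True``, the
    default): the scan compares shapes, with amplitude absorbed by GLM
    betas downstream.

    ``strategy='full'`` evaluates the complete Cartesian grid in
    lexicographic order (p1 outermost), keeping the first strict minimum,
    so ties break toward the lexicographically smallest parameter vector.
    ``strategy='coordinate'`` sweeps p1..p5 one at a time, repeating until
    no parameter changes (capped at ``max_sweeps`` sweeps).

    Returns ``(HRFParams, rmse)``.
    """
    ranges = ScanRanges() if ranges is None else ranges
    values, tr = _target_values(target)
    if np.ptp(values) == 0:
        raise ValueError("zero-variance target")
    duration = len(values) * tr
    tgt = _peak_normalize(values) if normalize else values

    def objective(p1, p2, p3, p4, p5):
        params = HRFParams(p1=p1, p2=p2, p3=p3, p4=p4, p5=p5,
                           p6=ranges.p6, p7=ranges.p7)
        model = sample_at_tr(params, tr, duration=duration)
        if normalize:
            model = _peak_normalize(model)
        return _rmse(model, tgt), params

    if strategy == "full":
        best_r, best_p = np.inf, None
        for combo in itertools.product(ranges.p1, ranges.p2, ranges.p3,
                                       ranges.p4, ranges.p5):
            r, p = objective(*combo)
            if r < best_r:
                best_r, best_p = r, p
        return best_p, best_r

    if strategy != "coordinate":
        raise ValueError(f"unknown strategy {strategy!r}")

    # start each coordinate at the grid point nearest the default value
    defaults = HRFParams()
    current = {}
    for name in ("p1", "p2", "p3", "p4", "p5"):
        g = getattr(ranges, name)
        current[name] = float(g[np.argmin(np.abs(g - getattr(defaults, name)))])
    best_r = None
    for _ in range(max_sweeps):
        changed = False
        for name in ("p1", "p2", "p3", "p4", "p5"):
            g = getattr(ranges, name)
            cand_r, cand_v = np.inf, current[name]
            for v in g:
                trial = dict(current)
                trial[name] = float(v)
                r, _ = objective(**trial)
                if r < cand_r:
                    cand_r, cand_v = r, float(v)
            if cand_v != current[name]:
                current[name] = cand_v
                changed = True
            best_r = cand_r
        if not changed:
            break
    best_r, best_p = objective(**current)
    return best_p, best_r


def shift_scan(target: EmpiricalResponse, base: HRFParams, shifts,
               normalize: bool = True) -> tuple:
    """Scan onset shifts (p6), returning ``(best_shift, rmse)``.

    Used for regions whose response is temporally offset from the reference
    region — in the study's data the main olfactory bulb, best captured by a
    2-s shift.  Ties break toward the smallest shift.
    """
    shifts = np.sort(np.asarray(shifts, dtype=float))
    if shifts.size == 0:
        raise ValueError("empty shift grid")
    if (shifts < 0).any() or (shifts > base.p7 / 2).any():
        raise ValueError("shifts must lie within [0, p7/2]")
    values, tr = _target_values(target)
    duration = len(values) * tr
    tgt = _peak_normalize(values) if normalize else values
    best_s, best_r = None, np.inf
    for s in shifts:
        model = sample_at_tr(base.replace(p6=float(s)), tr, duration=duration)
        if normalize:
            model = _peak_normalize(model)
        r = _rmse(model, tgt)
        if r < best_r:
            best_s, best_r = float(s), r
    return best_s, best_r
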