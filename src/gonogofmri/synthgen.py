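"""Synthetic behavioral sessions and BOLD runs with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes — it is the forward model every stage is tested against:

* blocks of 25 "go" + 25 "no-go" odor trials, interleaved in randomized
  order within blocks, with onset-to-onset intervals jittered uniformly on
  [5, 12.5] s;
* 1-s odor pulses; a 2-s response window opening 200 ms after final-valve
  opening;
* learning-dependent accuracy (saturating-exponential learning curve) and
  lognormal reaction times whose log-mean interpolates from a naive to an
  expert value with learning progress;
* sniff oscillations with phase reset and amplitude increase after odor
  onset once the animal is proficient; lick bursts as 6 Hz pulse trains;
* BOLD runs at TR 2.5 s and 200 x 200 x 300 um voxels containing
  region-specific condition responses convolved with a known HRF, plus
  AR(1) noise, slow cosine drift, and rigid-body motion with occasional
  spikes.

It deliberately omits realistic EPI artifacts, physiological noise beyond
AR(1)+drift, and schedule optimization; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from gonogofmri.core import (
    BOLDRun,
    ROISet,
    TRIAL_COLUMNS,
    validate_trial_table,
)
from gonogofmri.hrf import HRFParams, double_gamma, DT_MICRO

DEFAULT_REGIONS = ("VS", "DMS", "DLS", "HC", "MOB")

#: Region -> condition -> response amplitude, % of baseline.  Signs follow
#: the study's qualitative pattern: striatal regions respond positively to
#: Hit, the hippocampus negatively to Hit and positively to FA, and CR
#: responses are negative in the striatum and near zero in the hippocampus.
DEFAULT_ROI_BETAS = {
    "VS": {"Hit": 1.4, "FA": 0.45, "CR": -0.65},
    "DMS": {"Hit": 0.6, "FA": 0.3, "CR": -0.35},
    "DLS": {"Hit": 0.75, "FA": 0.0, "CR": -0.4},
    "HC": {"Hit": -0.3, "FA": 0.7, "CR": 0.0},
    "MOB": {"Hit": 1.0, "FA": 0.8, "CR": 0.3},
}


@dataclass
class SessionConfig:
    """Behavioral session parameters (times in seconds)."""

    n_blocks: int = 2
    trials_go_per_block: int = 25
    trials_nogo_per_block: int = 25
    iti_range: tuple = (5.0, 12.5)
    odor_duration: float = 1.0
    response_window_start: float = 0.2
    response_window_duration: float = 2.0
    onset_latency: float = 0.1          # valve opening -> steady-state odor
    learning_curve: dict = field(default_factory=lambda: {
        "p0": 0.5, "p_max": 0.92, "rate": 1.0 / 150.0})
    rt_model: dict = field(default_factory=lambda: {
        "mu_log_naive": float(np.log(1.0)),
        "mu_log_expert": float(np.log(0.55)),
        "sigma_log": 0.25})
    sniff_rate_hz: float = 4.0
    sample_rate_hz: float = 1000.0
    lick_burst_hz: float = 6.0
    lick_burst_duration: float = 1.0
    lick_pulse_width: float = 0.04
    water_delay: float = 0.05
    start_offset: float = 10.0          # first valve opening
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.iti_range
        if not lo < hi:
            raise ValueError("iti_range must satisfy lo < hi")
        for name in ("odor_duration", "response_window_start",
                     "response_window_duration", "sample_rate_hz",
                     "sniff_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lc = self.learning_curve
        if not (0 <= lc["p0"] <= lc["p_max"] <= 1):
            raise ValueError("learning curve requires 0 <= p0 <= p_max <= 1")
        window_end = self.response_window_start + self.response_window_duration
        if window_end > lo:
            raise ValueError(
                "response window extends past the minimum inter-trial interval")

    @property
    def n_trials_per_block(self) -> int:
        return self.trials_go_per_block + self.trials_nogo_per_block

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.n_trials_per_block


@dataclass
class GroundTruth:
    """Forward-model parameters for BOLD generation."""

    hrf: HRFParams = field(default_factory=HRFParams)
    roi_betas: dict = field(default_factory=lambda: {
        r: dict(v) for r, v in DEFAULT_ROI_BETAS.items()})
    roi_hrf_shift: dict = field(default_factory=lambda: {"MOB": 2.0})
    baseline: float = 100.0
    noise_sd: float = 0.5
    ar1_coef: float = 0.4
    drift_amp: float = 0.3
    drift_period: float = 128.0
    motion_amp_um: float = 10.0
    motion_spike_rate: float = 0.01     # per-volume probability
    motion_spike_scale: float = 250.0   # um
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hrf"] = asdict(self.hrf)
        return d


@dataclass
class SessionRecording:
    """Raw behavioral streams sharing a common time origin (t=0)."""

    sniff: np.ndarray
    lick: np.ndarray
    sample_rate_hz: float
    valve_events: list          # (open_time, close_time) pairs, time-ordered
    water_events: list          # delivery times
    odor_labels: list           # per-valve-event: "go" | "nogo"

    def __post_init__(self):
        opens = np.array([o for o, _ in self.valve_events])
        closes = np.array([c for _, c in self.valve_events])
        if len(opens) and ((closes <= opens).any()
                           or (opens[1:] < closes[:-1]).any()):
            raise ValueError("valve events must be non-overlapping and ordered")

    @property
    def duration(self) -> float:
        return len(self.sniff) / self.sample_rate_hz


def learning_accuracy(trial_index: np.ndarray, curve: dict) -> np.ndarray:
    """Per-trial P(correct): saturating exponential in the trial index."""
    k = np.asarray(trial_index, dtype=float)
    return curve["p_max"] - (curve["p_max"] - curve["p0"]) * np.exp(
        -curve["rate"] * k)


def make_session(config: SessionConfig) -> tuple:
    """Simulate one session; return ``(SessionRecording, TrialTable)``.

    The trial table is the ground-truth labeling: outcomes follow the
    Bernoulli accuracy model (P(correct) per the learning curve) and
    reaction times are lognormal with a learning-stage-interpolated
    log-mean, truncated to the response window.
    """
    rng = np.random.default_rng(config.seed)
    lc = config.learning_curve
    rt = config.rt_model
    win_lo = config.response_window_start
    win_hi = win_lo + config.response_window_duration

    rows = []
    onset = config.start_offset
    trial_idx = 0
    n_total = config.n_trials
    lick_times_all = []
    water_times = []
    valve_events = []
    odor_labels = []
    expert_flags = []
    for block in range(config.n_blocks):
        labels = (["go"] * config.trials_go_per_block
                  + ["nogo"] * config.trials_nogo_per_block)
        labels = list(rng.permutation(labels))
        for odor in labels:
            p_correct = float(learning_accuracy(np.array([trial_idx]), lc)[0])
            correct = rng.random() < p_correct
            progress = 1.0 - np.exp(-lc["rate"] * trial_idx)
            stim_onset = onset + config.onset_latency
            responded = (odor == "go" and correct) or (odor == "nogo" and not correct)
            reaction = np.nan
            first_lick = np.nan
            if responded:
                mu = (rt["mu_log_naive"]
                      + progress * (rt["mu_log_expert"] - rt["mu_log_naive"]))
                # truncate to keep the lick inside the response window:
                # RT is measured from stimulus onset, the window from valve
                # opening.
                lo = win_lo - config.onset_latency
                hi = win_hi - config.onset_latency
                for _ in range(100):
                    reaction = float(rng.lognormal(mu, rt["sigma_log"]))
                    if lo < reaction < hi:
                        break
                else:
                    reaction = float(np.clip(reaction, lo + 1e-3, hi - 1e-3))
                first_lick = stim_onset + reaction
                burst = first_lick + np.arange(
                    0, config.lick_burst_duration, 1.0 / config.lick_burst_hz)
                lick_times_all.extend(burst)
                if odor == "go":
                    water_times.append(first_lick + config.water_delay)
            outcome = {("go", True): "Hit", ("go", False): "Miss",
                       ("nogo", True): "CR", ("nogo", False): "FA"}[
                (odor, correct)]
            rows.append(dict(
                trial_id=trial_idx, block_id=block, session_id=0, odor=odor,
                valve_open_time=onset, stimulus_onset=stim_onset,
                first_lick_time=first_lick, reaction_time=reaction,
                outcome=outcome, censor_reason="none"))
            valve_events.append((onset, onset + config.odor_duration))
            odor_labels.append(odor)
            expert_flags.append(progress > 0.5)
            onset += rng.uniform(*config.iti_range)
            trial_idx += 1

    duration = onset + 30.0
    fs = config.sample_rate_hz
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # lick trace: rectangular pulses at each lick contact
    lick = np.zeros(n)
    width = max(1, int(round(config.lick_pulse_width * fs)))
    for lt in lick_times_all:
        i = int(round(lt * fs))
        lick[i:i + width] = 1.0

    # sniff trace: baseline oscillation; phase reset + amplitude boost after
    # odor onset in proficient ("expert") trials
    phase = 2 * np.pi * config.sniff_rate_hz * t + rng.uniform(0, 2 * np.pi)
    sniff = np.sin(phase)
    for (open_t, _), expert in zip(valve_events, expert_flags):
        if not expert:
            continue
        i0 = int(round(open_t * fs))
        i1 = min(n, i0 + int(round(1.0 * fs)))
        seg_t = t[i0:i1] - open_t
        sniff[i0:i1] = 1.5 * np.sin(2 * np.pi * config.sniff_rate_hz * seg_t)
    sniff += rng.normal(0, 0.05, size=n)

    recording = SessionRecording(
        sniff=sniff, lick=lick, sample_rate_hz=fs,
        valve_events=valve_events, water_events=water_times,
        odor_labels=odor_labels)
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    validate_trial_table(trials)
    assert len(trials) == n_total
    return recording, trials


def make_roiset(grid_shape: tuple = (24, 16, 10),
                regions=DEFAULT_REGIONS,
                voxel_size_um: tuple = (200.0, 200.0, 300.0)) -> ROISet:
    """Disjoint box-shaped masks for each region plus CSF and background.

    The default 24 x 16 x 10 grid at 200 x 200 x 300 um keeps the phantom
    desk-scale while preserving the acquisition's voxel anisotropy.
    """
    names = list(regions) + ["CSF", "background"]
    box = (2, 3, 3)
    nx, ny, nz = grid_shape
    per_x = max(1, nx // (box[0] + 1))
    capacity = per_x * max(1, ny // (box[1] + 1))
    if (nx < box[0] or ny < box[1] or nz < box[2]
            or capacity < len(names)):
        raise ValueError(
            f"grid {grid_shape} too small for {len(names)} disjoint ROIs")
    masks = {}
    for i, name in enumerate(names):
        gx, gy = i % per_x, i // per_x
        x0 = gx * (box[0] + 1)
        y0 = gy * (box[1] + 1)
        z0 = (nz - box[2]) // 2
        m = np.zeros(grid_shape, dtype=bool)
        m[x0:x0 + box[0], y0:y0 + box[1], z0:z0 + box[2]] = True
        masks[name] = m
    rois = ROISet(masks=masks, voxel_size_um=voxel_size_um)
    rois.check_disjoint()
    return rois


def condition_regressors(trials: pd.DataFrame, hrf: HRFParams, tr: float,
                         n_volumes: int, dt: float = DT_MICRO,
                         conditions=("Hit", "FA", "CR")) -> dict:
    """Stick functions at stimulus onsets convolved with the HRF kernel at
    microtime resolution, sampled at the TR grid.  Returns
    ``{condition: array of length n_volumes}``."""
    step = int(round(tr / dt))
    n_fine = n_volumes * step
    kernel = double_gamma(hrf, dt=dt)
    out = {}
    for cond in conditions:
        sticks = np.zeros(n_fine)
        onsets = trials.loc[trials["outcome"] == cond, "stimulus_onset"]
        for onset in onsets:
            i = int(round(onset / dt))
            if 0 <= i < n_fine:
                sticks[i] = 1.0
        conv = np.convolve(sticks, kernel)[:n_fine]
        out[cond] = conv[::step]
    return out


def ar1_noise(rng: np.random.Generator, n: int, sd: float,
              coef: float) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd`` and lag-1
    autocorrelation ``coef``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - coef ** 2)
    e = rng.normal(0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    for i in range(1, n):
        x[i] = coef * x[i - 1] + e[i]
    return x


def predicted_roi_series(region: str, trials: pd.DataFrame,
                         truth: GroundTruth, tr: float,
                         n_volumes: int) -> np.ndarray:
    """Noiseless forward prediction of a region's mean time series."""
    hrf = truth.hrf.replace(p6=truth.roi_hrf_shift.get(region, truth.hrf.p6))
    regs = condition_regressors(trials, hrf, tr, n_volumes)
    signal = np.zeros(n_volumes)
    for cond, beta in truth.roi_betas.get(region, {}).items():
        if cond in regs:
            signal += beta / 100.0 * regs[cond]
    return truth.baseline * (1.0 + signal)


def make_bold(trials: pd.DataFrame, rois: ROISet, truth: GroundTruth,
              tr: float = 2.5, n_volumes: int | None = None) -> tuple:
    """Generate a BOLD run plus a motion-parameter table.

    Every voxel of a region carries the region's predicted mean series;
    each voxel additionally receives AR(1)-filtered Gaussian noise and a
    random-phase cosine drift (zero-mean across realizations, so the
    expectation equals the noiseless prediction).  Returns
    ``(BOLDRun, MotionParams DataFrame)``.
    """
    rois.check_disjoint()
    last = trials["stimulus_onset"].max() if len(trials) else 0.0
    if n_volumes is None:
        n_volumes = int(np.ceil((last + truth.hrf.p7) / tr))
    if last >= n_volumes * tr:
        raise ValueError("trial onsets extend past the run duration")
    for region, betas in truth.roi_betas.items():
        if any(b <= -100.0 for b in betas.values()):
            raise ValueError(
                f"betas for {region} imply non-positive signal")
    rng = np.random.default_rng(truth.seed)
    shape = rois.shape
    data = np.full(shape + (n_volumes,), truth.baseline, dtype=float)
    for region in rois.names:
        if region == "background":
            data[rois[region]] = 0.0
            continue
        series = predicted_roi_series(region, trials, truth, tr, n_volumes)
        data[rois[region]] = series
    if truth.noise_sd > 0 or truth.drift_amp > 0:
        t = np.arange(n_volumes) * tr
        tissue = ~rois.masks.get("background", np.zeros(shape, dtype=bool))
        n_vox = int(tissue.sum())
        extra = np.zeros((n_vox, n_volumes))
        if truth.noise_sd > 0:
            a, sd = truth.ar1_coef, truth.noise_sd
            e = rng.normal(0, sd * np.sqrt(1 - a ** 2),
                           size=(n_vox, n_volumes))
            extra[:, 0] = rng.normal(0, sd, size=n_vox)
            for i in range(1, n_volumes):
                extra[:, i] = a * extra[:, i - 1] + e[:, i]
        if truth.drift_amp > 0:
            phase = rng.uniform(0, 2 * np.pi, size=n_vox)
            extra += truth.drift_amp * np.cos(
                2 * np.pi * t[None, :] / truth.drift_period + phase[:, None])
        data[tissue] += extra

    motion = _make_motion(rng, n_volumes, tr, truth)
    bold = BOLDRun(data=data, tr=tr, voxel_size_um=rois.voxel_size_um,
                   affine=rois.affine)
    return bold, motion


def _make_motion(rng: np.random.Generator, n_volumes: int, tr: float,
                 truth: GroundTruth) -> pd.DataFrame:
    """Smooth low-amplitude rigid-body motion plus occasional spikes."""
    t = np.arange(n_volumes) * tr
    cols = {}
    for i, name in enumerate(["trans_x", "trans_y", "trans_z"]):
        period = rng.uniform(60, 180)
        cols[name] = truth.motion_amp_um * np.sin(
            2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
    for name in ["rot_x", "rot_y", "rot_z"]:
        period = rng.uniform(60, 180)
        cols[name] = (truth.motion_amp_um / 5000.0) * np.sin(
            2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
    spikes = rng.random(n_volumes) < truth.motion_spike_rate
    spikes[0] = False
    for i in np.flatnonzero(spikes):
        axis = ["trans_x", "trans_y", "trans_z"][rng.integers(3)]
        cols[axis][i] += truth.motion_spike_scale * rng.choice([-1.0, 1.0])
    return pd.DataFrame(cols)
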