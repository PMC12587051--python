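"""Behavioral stream parsing: licks, trial taxonomy, performance, sniffing.

Converts raw session streams (lick detector trace, valve event times, sniff
pressure trace) into the go/no-go trial taxonomy — Hit, Miss, FA, CR, plus
a Nuisance class for correct rejections contaminated by licks adjacent to
(but outside) the response window — and derives per-block accuracy,
learning-stage splits, reaction-time tertiles, and lick-locked sniff
averages.

Timing conventions: the response window opens ``window_start`` (0.2 s) after
final-valve opening and lasts ``window_duration`` (2 s); odor concentration
reaches steady state about 100 ms after valve opening, so reaction time is
measured from ``valve_open_time + onset_latency``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from gonogofmri.core import TRIAL_COLUMNS, validate_trial_table


def detect_licks(lick_trace, sample_rate_hz: float, threshold: float = 0.5,
                 refractory: float = 0.05) -> np.ndarray:
    """Upward threshold-crossing times, separated by at least ``refractory``.

    A crossing is the first sample at or above threshold whose predecessor
    is below it; the event time is the rising edge.
    """
    x = np.asarray(lick_trace, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("lick trace contains non-finite samples")
    above = x >= threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        rising = np.concatenate([[0], rising])
    times = rising / sample_rate_hz
    if refractory > 0 and len(times):
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory:
                kept.append(t)
        times = np.array(kept)
    return times


def classify_trials(valve_events, odor_labels, lick_times,
                    window_start: float = 0.2, window_duration: float = 2.0,
                    onset_latency: float = 0.1,
                    adjacency: float = 1.0) -> pd.DataFrame:
    """Label each valve event as Hit / Miss / FA / CR / Nuisance.

    * go + lick in window -> Hit; go + no in-window lick -> Miss (flagged
      ``random_lick`` if a lick fell in the adjacency region instead);
    * no-go + lick in window -> FA; no-go + none -> CR, demoted to Nuisance
      (``adjacent_lick``) if licks occur inside the adjacency window
      ``[odor onset - adjacency, window end + adjacency]`` but outside the
      response window;
    * reaction time = first in-window lick − stimulus onset, where the
      stimulus onset is ``valve_open + onset_latency``.
    """
    if len(valve_events) != len(odor_labels):
        raise ValueError("odor label missing for a valve event")
    licks = np.sort(np.asarray(lick_times, dtype=float))
    rows = []
    for i, ((open_t, close_t), odor) in enumerate(zip(valve_events, odor_labels)):
        if odor not in ("go", "nogo"):
            raise ValueError(f"unknown odor label {odor!r}")
        stim_onset = open_t + onset_latency
        win_lo = open_t + window_start
        win_hi = win_lo + window_duration
        adj_lo = stim_onset - adjacency
        adj_hi = win_hi + adjacency
        in_win = licks[(licks >= win_lo) & (licks <= win_hi)]
        adjacent = licks[(licks >= adj_lo) & (licks <= adj_hi)]
        stray = np.setdiff1d(adjacent, in_win)
        reaction = np.nan
        first_lick = np.nan
        censor = "none"
        if odor == "go":
            if len(in_win):
                outcome = "Hit"
                first_lick = in_win[0]
                reaction = first_lick - stim_onset
            else:
                outcome = "Miss"
                if len(stray):
                    censor = "random_lick"
                    first_lick = stray[0]
        else:
            if len(in_win):
                outcome = "FA"
                first_lick = in_win[0]
                reaction = first_lick - stim_onset
            elif len(stray):
                outcome = "Nuisance"
                censor = "adjacent_lick"
                first_lick = stray[0]
            else:
                outcome = "CR"
        rows.append(dict(
            trial_id=i, block_id=0, session_id=0, odor=odor,
            valve_open_time=open_t, stimulus_onset=stim_onset,
            first_lick_time=first_lick, reaction_time=reaction,
            outcome=outcome, censor_reason=censor))
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    validate_trial_table(trials)
    return trials


def assign_blocks(trials: pd.DataFrame, trials_per_block: int) -> pd.DataFrame:
    """Assign consecutive block ids given a fixed block size."""
    out = trials.copy()
    out["block_id"] = out.index // trials_per_block
    return out


SCOREABLE = ("Hit", "Miss", "FA", "CR")


@dataclass
class BehaviorSummary:
    """Per-block accuracy, per-session mean reaction time, stage labels."""

    block_accuracy: pd.Series         # block_id -> fraction correct
    session_mean_rt: pd.Series        # session_id -> mean Hit RT (s)
    stage_labels: pd.Series           # block_id -> naive | mid | expert


def performance_curve(trials: pd.DataFrame, n_stage_blocks: int = 10,
                      criterion: float = 0.80) -> BehaviorSummary:
    """Per-block accuracy ``(n_Hit + n_CR) / n_scoreable``.

    Nuisance trials are excluded from both numerator and denominator.  The
    performance ``criterion`` is recorded only via stage labels and does not
    enter any downstream analysis.
    """
    scored = trials[trials["outcome"].isin(SCOREABLE)]
    if scored.empty:
        raise ValueError("no scoreable trials")
    acc = {}
    for block, grp in scored.groupby("block_id"):
        if len(grp) == 0:
            raise ValueError(f"block {block} has zero scoreable trials")
        acc[block] = ((grp["outcome"] == "Hit").sum()
                      + (grp["outcome"] == "CR").sum()) / len(grp)
    empty_blocks = set(trials["block_id"]) - set(acc)
    if empty_blocks:
        raise ValueError(f"blocks with zero scoreable trials: {sorted(empty_blocks)}")
    accuracy = pd.Series(acc).sort_index()
    hits = trials[trials["outcome"] == "Hit"]
    mean_rt = hits.groupby("session_id")["reaction_time"].mean()
    blocks = accuracy.index.to_numpy()
    labels = pd.Series("mid", index=accuracy.index, dtype=object)
    if len(blocks) >= 2 * n_stage_blocks:
        naive_ids, expert_ids = stage_split(trials, n_stage_blocks)
        labels.loc[list(naive_ids)] = "naive"
        labels.loc[list(expert_ids)] = "expert"
    return BehaviorSummary(block_accuracy=accuracy, session_mean_rt=mean_rt,
                           stage_labels=labels)


def stage_split(trials: pd.DataFrame, n_blocks: int = 10) -> tuple:
    """First ``n_blocks`` block ids (naive stage) and last ``n_blocks``
    (expert stage).  Raises if the stages would overlap."""
    blocks = np.sort(trials["block_id"].unique())
    if len(blocks) < 2 * n_blocks:
        raise ValueError(
            f"{len(blocks)} blocks cannot support disjoint naive/expert "
            f"stages of {n_blocks} blocks each")
    return list(blocks[:n_blocks]), list(blocks[-n_blocks:])


def rt_tertiles(trials: pd.DataFrame) -> tuple:
    """Fastest and slowest third of Hit trials, per block.

    Within each block the Hit trials are sorted by reaction time (ties
    broken by trial order, earlier ranking faster); the fastest and slowest
    ``floor(n/3)`` form the fast and slow sets.  Blocks with fewer than
    three Hits contribute nothing.  Returns ``(fast_ids, slow_ids)``.
    """
    fast, slow = [], []
    hits = trials[trials["outcome"] == "Hit"]
    for _, grp in hits.groupby("block_id"):
        k = len(grp) // 3
        if k == 0:
            continue
        order = grp.sort_values(["reaction_time", "trial_id"],
                                kind="stable")["trial_id"].to_list()
        fast.extend(order[:k])
        slow.extend(order[-k:])
    return fast, slow


def sniff_preprocess(sniff_trace, sample_rate_hz: float,
                     lowpass_hz: float = 20.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth lowpass of the sniff pressure trace.

    Zero-phase (forward-backward) filtering avoids introducing a group
    delay that would bias sniff-locked timing estimates.
    """
    if sample_rate_hz < 2 * lowpass_hz:
        raise ValueError("sampling rate below Nyquist for requested cutoff")
    x = np.asarray(sniff_trace, dtype=float)
    b, a = butter(order, lowpass_hz, btype="low", fs=sample_rate_hz)
    return filtfilt(b, a, x)


def sniff_lick_average(trials: pd.DataFrame, sniff_trace,
                       sample_rate_hz: float, window: tuple = (-2.0, 1.0),
                       stages: dict | None = None,
                       lowpass_hz: float = 20.0) -> dict:
    """Mean lowpassed sniff segment aligned to the first lick (lick at t=0)
    of each Hit trial, computed separately per learning stage.

    ``stages`` maps stage name -> iterable of block ids; default is a
    single ``"all"`` stage.  A stage without usable Hit trials yields
    ``None`` (flagged, not an exception).  Returns
    ``{stage: (time_axis, mean_trace) | None}``.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be increasing")
    filtered = sniff_preprocess(sniff_trace, sample_rate_hz, lowpass_hz)
    n = len(filtered)
    i_lo = int(round(lo * sample_rate_hz))
    i_hi = int(round(hi * sample_rate_hz))
    t_axis = np.arange(i_lo, i_hi) / sample_rate_hz
    if stages is None:
        stages = {"all": trials["block_id"].unique()}
    out = {}
    for stage, blocks in stages.items():
        sel = trials[(trials["outcome"] == "Hit")
                     & trials["block_id"].isin(list(blocks))
                     & trials["first_lick_time"].notna()]
        segs = []
        for lick_t in sel["first_lick_time"]:
            c = int(round(lick_t * sample_rate_hz))
            if c + i_lo < 0 or c + i_hi > n:
                raise ValueError("alignment window extends beyond recording")
            segs.append(filtered[c + i_lo:c + i_hi])
        out[stage] = (t_axis, np.mean(segs, axis=0)) if segs else None
    return out
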