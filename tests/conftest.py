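"""Shared fixtures: small synthetic sessions, phantoms, and forward models."""

import numpy as np
import pandas as pd
import pytest

from gonogofmri.core import TRIAL_COLUMNS
from gonogofmri.hrf import HRFParams
from gonogofmri.synthgen import GroundTruth, SessionConfig, make_roiset, make_session

TR = 2.5


def trial_table(onsets, outcomes, odors=None, block_ids=None,
                onset_latency=0.1, rts=None):
    """Build a valid trial table from onset/outcome lists (test helper)."""
    n = len(onsets)
    odors = odors or ["go" if o in ("Hit", "Miss") else "nogo"
                      for o in outcomes]
    rows = []
    for i in range(n):
        responded = outcomes[i] in ("Hit", "FA")
        rt = (rts[i] if rts is not None else 0.5) if responded else np.nan
        rows.append(dict(
            trial_id=i, block_id=block_ids[i] if block_ids else 0,
            session_id=0, odor=odors[i], valve_open_time=onsets[i],
            stimulus_onset=onsets[i] + onset_latency,
            first_lick_time=onsets[i] + onset_latency + rt if responded
            else np.nan,
            reaction_time=rt, outcome=outcomes[i], censor_reason="none"))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@pytest.fixture(scope="session")
def small_rois():
    return make_roiset(grid_shape=(24, 16, 10))


@pytest.fixture(scope="session")
def default_session():
    """One 2-block session with the default learning model, fixed seed."""
    cfg = SessionConfig(n_blocks=2, seed=11)
    recording, trials = make_session(cfg)
    return cfg, recording, trials


@pytest.fixture
def noiseless_truth():
    return GroundTruth(noise_sd=0.0, drift_amp=0.0, motion_spike_rate=0.0,
                       motion_amp_um=0.0, roi_hrf_shift={}, seed=0)


@pytest.fixture(scope="session")
def mouse_hrf():
    return HRFParams()


def grid_trials(n_events, spacing_vol=6, start_vol=4, outcome="Hit",
                tr=TR):
    """Trials with stimulus onsets exactly on the TR grid (for FIR/OLS
    exactness checks)."""
    onsets = [(start_vol + i * spacing_vol) * tr for i in range(n_events)]
    t = trial_table([o - 0.1 for o in onsets],
                    [outcome] * n_events)
    t["stimulus_onset"] = onsets
    return t
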