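"""Pipeline configuration: one nested mapping with documented units.

The configuration round-trips losslessly through YAML/JSON.  Every value
carries its unit in the key comment below; acquisition constants default to
the study's protocol (TR 2.5 s, 200 x 200 x 300 um voxels).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

DEFAULTS = {
    "paths": {
        "out": "output",
    },
    "acquisition": {
        "tr": 2.5,                       # s
        "voxel_size_um": [200.0, 200.0, 300.0],
    },
    "behavior": {
        "window_start": 0.2,             # s after valve opening
        "window_duration": 2.0,          # s
        "onset_latency": 0.1,            # s, valve -> steady-state odor
        "adjacency": 1.0,                # s, CR-reassignment window margin
        "n_stage_blocks": 10,            # blocks per naive/expert stage
        "lick_threshold": 0.5,           # lick-trace units
        "lick_refractory": 0.05,         # s
    },
    "hrf": {
        "strategy": "coordinate",        # or "full"
        "normalize": True,
        "length": 30.0,                  # s
    },
    "glm": {
        "q": 0.05,
        "extent": 5,                     # voxels
        "smoothing_fwhm_um": 600.0,
        "prewhiten": False,
        "highpass": False,
    },
    "motion": {
        "threshold_um": 200.0,           # censor above one voxel diameter
        "sphere_radius_um": 5000.0,
        "trial_window": 2.2,             # s, valve opening -> window end
    },
    "simulate": {
        "n_blocks": 2,
        "grid_shape": [24, 16, 10],
    },
    "seed": 0,
}


@dataclass
class PipelineConfig:
    """Nested configuration with study defaults; unknown keys rejected."""

    values: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key):
        return self.values[key]

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "PipelineConfig":
        cfg = copy.deepcopy(DEFAULTS)
        for section, vals in (overrides or {}).items():
            if section not in cfg:
                raise KeyError(f"unknown config section {section!r}")
            if isinstance(vals, dict):
                for k, v in vals.items():
                    if k not in cfg[section]:
                        raise KeyError(f"unknown config key {section}.{k}")
                    cfg[section][k] = v
            else:
                cfg[section] = vals
        return cls(values=cfg)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=False)

    def to_dict(self) -> dict:
        return copy.deepcopy(self.values)
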