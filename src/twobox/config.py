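"""Pipeline configuration: every tunable of the analysis with its default.

Defaults are the values the analysis protocol fixes: 3 cm bins, 5 cm Gaussian
smoothing truncated at 9 cm, 0.1 s dwell floor, 5/100 cm/s speed filters,
0.2% ISI-violation bound at 2 ms, 0.1-5 Hz baseline rates, 250 us
peak-to-trough, 16-pixel / 40%-of-peak / 1 Hz fields, 50% messy bound, 100
circular shuffles with a 20 s margin, 10,000 null pairs at the 95th
percentile, a 0.375 spatial prescreen and 0.5 / 0.1 posterior rules for
duplicate tracking.  Unknown keys are rejected so a typo cannot silently
fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml


@dataclass
class PipelineConfig:
    # rate maps
    bin_size: float = 3.0
    smoothing_sigma: float = 5.0
    smoothing_cutoff: float = 9.0
    min_dwell: float = 0.1
    speed_min: float = 5.0
    speed_max: float = 100.0
    # unit QC
    isi_refractory: float = 0.002
    isi_max_fraction: float = 0.002
    rate_min: float = 0.1
    rate_max: float = 5.0
    peak_trough_min_us: float = 250.0
    # place fields
    field_min_pixels: int = 16
    field_frac_of_peak: float = 0.4
    field_peak_min: float = 1.0
    messy_fraction: float = 0.5
    field_connectivity: int = 8
    # shuffle test
    n_shuffles: int = 100
    shuffle_margin: float = 20.0
    info_percentile: float = 95.0
    # null distributions / classification
    null_n: int = 10000
    null_percentile: float = 95.0
    min_joint_bins: int = 20
    # duplicate tracking
    spatial_prescreen: float = 0.375
    posterior_min: float = 0.5
    posterior_gap: float = 0.1
    # randomness
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        """Short stable digest identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
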