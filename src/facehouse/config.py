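"""Pipeline configuration: every stage parameter with its standard default.

Defaults are the analysis constants of the study protocol: 80% global
signal mask fraction, 8 mm FWHM smoothing, 128 s high-pass cutoff, cluster
forming z = 3.1 with voxel FWE alpha .05, framewise displacement threshold
0.3 mm with a 70% low-motion frame requirement, and B = 10,000
permutations.  Unknown keys in a config file are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import yaml


@dataclass
class PipelineConfig:
    # cohort
    n_children: int = 1000
    age_range: tuple = (8.0, 11.0)
    sex_proportion_girls: float = 0.5
    plant_default_effects: bool = True
    # scan / simulation
    n_subjects: int = 8
    grid_dims: tuple = (24, 24, 14)
    voxel_size_mm: float = 2.5
    tr_s: float = 1.0
    n_volumes: int = 389
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 1.0
    # first level
    mask_fraction: float = 0.80
    fwhm_mm: float = 8.0
    hp_cutoff_s: float = 128.0
    fd_threshold_mm: float = 0.3
    low_motion_fraction: float = 0.70
    fd_radius_mm: float = 50.0
    # group level
    cluster_forming_z: float = 3.1
    fwe_alpha: float = 0.05
    cluster_extent_k: int | None = None  # None -> Monte Carlo estimate
    k_n_sim: int = 500
    overlap_threshold_t: float = 1.96
    # inference
    n_perm: int = 10_000
    alpha: float = 0.05
    # atlas
    atlas_splits: tuple = (2, 2, 2)
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        self.age_range = tuple(self.age_range)
        self.grid_dims = tuple(self.grid_dims)
        self.atlas_splits = tuple(self.atlas_splits)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
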