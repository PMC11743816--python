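"""Shared containers for the face/house task pipeline.

The pipeline moves three kinds of objects between stages: a behavioral cohort
table (a plain :class:`pandas.DataFrame`), 4D BOLD-like volume series, and the
planted ground truth that makes synthetic runs verifiable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Emotions probed by the 40-item emotion-labeling test (8 items each).
EMOTIONS = ("happy", "sad", "angry", "fearful", "neutral")

#: Stimulus categories shown in the scanner task.
FACE_CONDITIONS = ("happy", "fearful", "neutral")
CONDITIONS = FACE_CONDITIONS + ("houses",)

#: Attention-check stimulus (button press target); not modeled in the GLM.
CIRCLE = "circle"


@dataclass
class VolumeSeries:
    """A 4D intensity grid with its spatial metadata and motion trace.

    Attributes
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel intensities.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : ndarray, shape (4, 4)
        Voxel-to-mm map (RAS convention, 0-based voxel indices).
    realignment : ndarray, shape (t, 6)
        Per-frame rigid-body parameters: 3 translations (mm) then 3
        rotations (rad).
    """

    data: np.ndarray
    voxel_size: tuple
    affine: np.ndarray
    realignment: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.realignment = np.asarray(self.realignment, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, frame)")
        if self.realignment.shape != (self.data.shape[3], 6):
            raise ValueError(
                "realignment must have one 6-parameter row per frame "
                f"(got {self.realignment.shape} for {self.data.shape[3]} frames)"
            )
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class GroundTruth:
    """Planted truth behind a synthetic cohort or volume series.

    ``behavioral_effects`` maps outcome name -> (age slope, girl-boy
    difference) in outcome units.  ``amplitude_maps`` maps condition name ->
    3D amplitude grid (signal units; zero outside the declared blobs).
    ``high_motion_frames`` lists frame indices with injected motion spikes.
    """

    behavioral_effects: dict = field(default_factory=dict)
    amplitude_maps: dict = field(default_factory=dict)
    high_motion_frames: list = field(default_factory=list)
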