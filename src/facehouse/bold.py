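"""Forward simulation of block-design BOLD-like 4D volumes.

data = baseline
     + sum over conditions of amplitude_map x (HRF-convolved boxcar)
     + low-frequency drift
     + AR(1) Gaussian noise,

with a per-frame 6-parameter realignment trace and an optional transient
signal drop (frames x region x factor) to exercise the downstream
global-signal mask exclusion.  The drift is spanned by the two lowest-order
discrete-cosine basis functions, so the first-level high-pass regressors
remove it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import CONDITIONS, GroundTruth, VolumeSeries
from .hrf import condition_regressor, dct_highpass_basis
from .task import TaskDesign


@dataclass
class Blob:
    """A spherical activation site with per-condition response amplitudes."""

    center: tuple  # voxel indices
    radius: float  # voxels
    amplitudes: dict  # condition -> signal units


def default_blobs() -> list:
    """Three planted sites: face-selective, happy-biased, fear-biased."""
    return [
        Blob((6, 6, 5), 2.5, {"happy": 2.0, "fearful": 2.0, "neutral": 2.0, "houses": 0.5}),
        Blob((17, 6, 8), 2.5, {"happy": 1.5, "fearful": 0.5, "neutral": 0.5, "houses": 0.5}),
        Blob((11, 17, 8), 2.5, {"happy": 0.5, "fearful": 1.5, "neutral": 0.5, "houses": 0.5}),
    ]


@dataclass
class ScanConfig:
    """Acquisition and noise model of one simulated run.

    Defaults mirror the acquisition the task was designed for (TR = 1 s,
    one run of 389 volumes) on a deliberately small grid.  ``motion_profile``
    is either None (still subject), an explicit (n_volumes, 6) array, or a
    dict with keys ``step_mm``, ``step_rad`` (random-walk steps) and
    optionally ``spike_frames``, ``spike_mm`` for injected high-motion
    frames.  ``signal_drop_spec`` is ``(frames, (center, radius), factor)``.
    """

    grid_dims: tuple = (24, 24, 14)
    voxel_size: float = 2.5
    tr: float = 1.0
    n_volumes: int = 389
    baseline: float = 100.0
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 1.0
    blobs: list = field(default_factory=default_blobs)
    motion_profile: object = None
    signal_drop_spec: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def amplitude_maps(scan: ScanConfig) -> dict:
    """Per-condition 3D amplitude grids implied by the blob list."""
    amps = {c: np.zeros(scan.grid_dims) for c in CONDITIONS}
    for blob in scan.blobs:
        m = sphere_mask(scan.grid_dims, blob.center, blob.radius)
        for cond, a in blob.amplitudes.items():
            amps[cond][m] += a
    return amps


def _realignment_trace(scan: ScanConfig, rng) -> tuple:
    n = scan.n_volumes
    prof = scan.motion_profile
    if prof is None:
        return np.zeros((n, 6)), []
    if isinstance(prof, np.ndarray):
        if prof.shape != (n, 6):
            raise ValueError("explicit motion_profile must be (n_volumes, 6)")
        return prof.astype(float), []
    step_mm = prof.get("step_mm", 0.02)
    step_rad = prof.get("step_rad", 2e-4)
    trace = np.cumsum(
        rng.normal(0.0, 1.0, (n, 6)) * ([step_mm] * 3 + [step_rad] * 3), axis=0
    )
    spikes = list(prof.get("spike_frames", []))
    spike_mm = prof.get("spike_mm", 1.0)
    for f in spikes:
        trace[f:, 0] += spike_mm * (1 if f % 2 == 0 else -1)
    return trace, spikes


def simulate_bold(design: TaskDesign, scan: ScanConfig) -> tuple:
    """Simulate one run; returns (VolumeSeries, GroundTruth)."""
    duration = scan.tr * scan.n_volumes
    if design.duration > duration + 1e-9:
        raise ValueError(
            f"task design ({design.duration:.1f} s) longer than scan ({duration:.1f} s)"
        )
    rng = np.random.default_rng(scan.seed)
    amps = amplitude_maps(scan)

    data = np.full(scan.grid_dims + (scan.n_volumes,), scan.baseline)
    for cond in CONDITIONS:
        spans = design.condition_spans(cond)
        if not spans or not np.any(amps[cond]):
            continue
        reg = condition_regressor(spans, scan.tr, scan.n_volumes)
        data += amps[cond][..., None] * reg[None, None, None, :]

    if scan.drift_amplitude:
        basis = dct_highpass_basis(scan.n_volumes, scan.tr, cutoff_s=128.0)[:, :2]
        w = rng.normal(0.0, 1.0, basis.shape[1])
        data += scan.drift_amplitude * (basis @ w)[None, None, None, :]

    if scan.noise_sd > 0:
        phi = scan.ar1_coefficient
        innov_sd = scan.noise_sd * np.sqrt(1.0 - phi**2)
        innov = rng.normal(0.0, innov_sd, data.shape)
        data += signal.lfilter([1.0], [1.0, -phi], innov, axis=-1)

    realignment, spikes = _realignment_trace(scan, rng)

    if scan.signal_drop_spec is not None:
        frames, (center, radius), factor = scan.signal_drop_spec
        region = sphere_mask(scan.grid_dims, center, radius)
        for f in frames:
            data[..., f][region] *= factor

    affine = np.diag([scan.voxel_size] * 3 + [1.0])
    series = VolumeSeries(
        data=data,
        voxel_size=(scan.voxel_size,) * 3,
        affine=affine,
        realignment=realignment,
    )
    truth = GroundTruth(amplitude_maps=amps, high_motion_frames=spikes)
    return series, truth
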