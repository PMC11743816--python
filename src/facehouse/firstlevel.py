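"""Per-subject (first-level) GLM on a 4D series.

Design-matrix construction (condition boxcars convolved with the canonical
HRF, realignment regressors, discrete-cosine high-pass basis with a 128 s
cutoff, intercept), global-signal masking with hole detection, voxelwise
OLS, contrast maps, Gaussian smoothing, and framewise-displacement motion
QC.  Plain OLS is used throughout (no autocorrelation prewhitening).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CONDITIONS, VolumeSeries
from .hrf import condition_regressor, dct_highpass_basis
from .task import TaskDesign

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class DesignMatrix:
    values: np.ndarray  # frames x regressors
    names: list

    def __post_init__(self):
        if self.values.shape[1] != len(self.names):
            raise ValueError("names must match columns")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass
class SignalMask:
    """Voxels retained by the global-signal threshold."""

    include: np.ndarray  # boolean 3D
    global_fraction: float
    has_holes: bool

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())


@dataclass
class ContrastSpec:
    """Named weights over condition regressors."""

    name: str
    weights: dict  # regressor name -> weight

    def __post_init__(self):
        if not any(self.weights.values()):
            raise ValueError("contrast must have at least one nonzero weight")


#: The four standard contrasts of the face/house task.
CONTRASTS = {
    "faces>houses": ContrastSpec(
        "faces>houses",
        {"happy": 1 / 3, "fearful": 1 / 3, "neutral": 1 / 3, "houses": -1.0},
    ),
    "happy>neutral": ContrastSpec("happy>neutral", {"happy": 1.0, "neutral": -1.0}),
    "fearful>neutral": ContrastSpec("fearful>neutral", {"fearful": 1.0, "neutral": -1.0}),
    "fearful>happy": ContrastSpec("fearful>happy", {"fearful": 1.0, "happy": -1.0}),
}


@dataclass
class ContrastMap:
    values: np.ndarray  # 3D; NaN outside mask
    subject_id: str
    contrast: str
    smoothed: bool = False
    fwhm_mm: float = 0.0


@dataclass
class MotionSummary:
    fd: np.ndarray  # per-frame framewise displacement, mm (first frame 0)
    frac_high: float
    low_motion: bool
    threshold_mm: float
    max_high_fraction: float


def compute_signal_mask(series: VolumeSeries, fraction: float = 0.8) -> SignalMask:
    """Keep voxels whose temporal-mean signal reaches ``fraction`` of the
    global mean (computed over nonzero voxels).

    ``has_holes`` is True when some excluded 6-connected region is not
    reachable from the volume border - the signature of a signal drop
    inside the head rather than background air.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    tmean = series.data.mean(axis=3)
    nonzero = tmean != 0
    if not np.any(nonzero):
        raise ValueError("series is all zero")
    global_mean = tmean[nonzero].mean()
    include = tmean >= fraction * global_mean

    excluded = ~include
    labels, n_lab = ndimage.label(excluded, structure=ndimage.generate_binary_structure(3, 1))
    border = np.zeros_like(excluded)
    for ax in range(3):
        sl = [slice(None)] * 3
        for idx in (0, -1):
            sl[ax] = idx
            border[tuple(sl)] = True
    border_labels = set(np.unique(labels[border & excluded]))
    all_labels = set(range(1, n_lab + 1))
    has_holes = bool(all_labels - border_labels)
    return SignalMask(include=include, global_fraction=fraction, has_holes=has_holes)


def build_design_matrix(
    design: TaskDesign | None,
    realignment: np.ndarray | None,
    tr: float,
    n_frames: int,
    hp_cutoff_s: float = 128.0,
) -> DesignMatrix:
    """Assemble the first-level design matrix.

    Columns, in order: one HRF-convolved boxcar per stimulus category
    present in the design (circle events excluded), the six realignment
    parameters (omitted when ``realignment`` is None or identically zero),
    the DCT high-pass basis for periods above ``hp_cutoff_s``, and the
    intercept last.
    """
    cols, names = [], []
    if design is not None:
        if design.duration > tr * n_frames + 1e-9:
            raise ValueError("design extends beyond the scan")
        for cond in CONDITIONS:
            spans = design.condition_spans(cond)
            if spans:
                cols.append(condition_regressor(spans, tr, n_frames))
                names.append(cond)
    if realignment is not None:
        realignment = np.asarray(realignment, dtype=float)
        if realignment.shape != (n_frames, 6):
            raise ValueError("realignment must be (n_frames, 6)")
        for j, label in enumerate(["tx", "ty", "tz", "rx", "ry", "rz"]):
            col = realignment[:, j]
            if np.any(col):
                cols.append(col)
                names.append(f"motion_{label}")
    dct = dct_highpass_basis(n_frames, tr, hp_cutoff_s)
    for k in range(dct.shape[1]):
        cols.append(dct[:, k])
        names.append(f"dct_{k + 1}")
    cols.append(np.ones(n_frames))
    names.append("intercept")

    values = np.column_stack(cols)
    if np.linalg.matrix_rank(values) < values.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(values=values, names=names)


@dataclass
class GLMResult:
    """Voxelwise OLS estimates within the signal mask."""

    betas: dict  # regressor name -> 3D map (NaN outside mask)
    sigma2: np.ndarray  # residual variance map
    df: int
    design: DesignMatrix
    mask: SignalMask
    _xtx_inv: np.ndarray

    def contrast_t(self, spec: ContrastSpec) -> np.ndarray:
        """Voxelwise t statistic for a contrast of condition regressors."""
        w = _weight_vector(spec, self.design.names)
        eff = sum(w_j * self.betas[n] for n, w_j in zip(self.design.names, w) if w_j)
        var_scale = float(w @ self._xtx_inv @ w)
        with np.errstate(invalid="ignore", divide="ignore"):
            return eff / np.sqrt(self.sigma2 * var_scale)


def fit_glm(series: VolumeSeries, X: DesignMatrix, mask: SignalMask) -> GLMResult:
    """Ordinary least squares per voxel within the mask."""
    n_frames, p = X.values.shape
    if n_frames < p:
        raise ValueError("fewer frames than regressors")
    if series.n_frames != n_frames:
        raise ValueError("design matrix frame count must match the series")
    Y = series.data[mask.include]  # voxels x frames
    pinv = np.linalg.pinv(X.values)
    B = Y @ pinv.T  # voxels x p
    resid = Y - B @ X.values.T
    df = n_frames - p
    s2 = (resid**2).sum(axis=1) / df

    shape = series.shape
    betas = {}
    for j, name in enumerate(X.names):
        m = np.full(shape, np.nan)
        m[mask.include] = B[:, j]
        betas[name] = m
    sigma2 = np.full(shape, np.nan)
    sigma2[mask.include] = s2
    xtx_inv = np.linalg.inv(X.values.T @ X.values)
    return GLMResult(betas=betas, sigma2=sigma2, df=df, design=X, mask=mask, _xtx_inv=xtx_inv)


def _weight_vector(spec: ContrastSpec, names: list) -> np.ndarray:
    w = np.zeros(len(names))
    for name, weight in spec.weights.items():
        if name not in names:
            raise ValueError(f"unknown regressor {name!r} in contrast {spec.name!r}")
        w[names.index(name)] = weight
    return w


def compute_contrast(
    glm: GLMResult, spec: ContrastSpec, subject_id: str = ""
) -> ContrastMap:
    """Weighted combination of condition beta maps."""
    w = _weight_vector(spec, glm.design.names)
    values = sum(
        w_j * glm.betas[n] for n, w_j in zip(glm.design.names, w) if w_j
    )
    return ContrastMap(values=values, subject_id=subject_id, contrast=spec.name)


def smooth_volume(
    values: np.ndarray, fwhm_mm: float = 8.0, voxel_size=(2.5, 2.5, 2.5)
) -> np.ndarray:
    """Separable Gaussian smoothing with zero padding at the edges.

    NaN voxels (outside-mask) are treated as zero during filtering and
    restored to NaN afterwards.  ``fwhm_mm=0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return values
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma = FWHM_TO_SIGMA * fwhm_mm / voxel_size
    nan_mask = np.isnan(values)
    filled = np.where(nan_mask, 0.0, values)
    out = ndimage.gaussian_filter(filled, sigma=sigma, mode="constant", cval=0.0)
    if nan_mask.any():
        out[nan_mask] = np.nan
    return out


def framewise_displacement(
    realignment: np.ndarray,
    radius_mm: float = 50.0,
    fd_threshold_mm: float = 0.3,
    max_high_fraction: float = 0.3,
) -> MotionSummary:
    """Power-style framewise displacement from 6 rigid-body parameters.

    fd_t = sum |d translation_i| + radius_mm * sum |d rotation_i| with the
    first frame fixed at 0.  A subject is low motion when at most
    ``max_high_fraction`` of frames exceed ``fd_threshold_mm``.
    """
    realignment = np.asarray(realignment, dtype=float)
    if realignment.ndim != 2 or realignment.shape[1] != 6:
        raise ValueError("realignment must have 6 columns")
    diffs = np.abs(np.diff(realignment, axis=0))
    fd = np.concatenate(
        [[0.0], diffs[:, :3].sum(axis=1) + radius_mm * diffs[:, 3:].sum(axis=1)]
    )
    frac_high = float(np.mean(fd > fd_threshold_mm))
    return MotionSummary(
        fd=fd,
        frac_high=frac_high,
        low_motion=frac_high <= max_high_fraction,
        threshold_mm=fd_threshold_mm,
        max_high_fraction=max_high_fraction,
    )
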