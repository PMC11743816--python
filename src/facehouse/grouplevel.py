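"""Across-subject (second-level) statistics on contrast maps.

One-sample t maps, combined voxel-FWE + cluster-extent thresholding, Monte
Carlo estimation of the cluster-extent threshold k, and subject-overlap
maps.  Voxel-level family-wise error is controlled by Bonferroni over
in-mask voxels, a desk-scale stand-in for random-field FWE; cluster-forming
uses the z-equivalent of the group t at the conventional z = 3.1
(one-sided p = .001).  Positive and negative directions are thresholded
separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

#: 18-connectivity (faces + edges) for cluster components.
CLUSTER_STRUCTURE = ndimage.generate_binary_structure(3, 2)


@dataclass
class GroupStatMap:
    t: np.ndarray  # 3D; NaN outside the analysis mask
    df: int
    n_subjects: int
    contrast: str
    mask: np.ndarray  # analysis mask (intersection of subject masks)
    zero_variance: np.ndarray  # flagged voxels with sd == 0


@dataclass
class ThresholdSpec:
    voxel_fwe_alpha: float = 0.05
    cluster_forming_z: float = 3.1
    cluster_extent_k: int = 1
    connectivity: np.ndarray = None

    def __post_init__(self):
        if not 0.0 < self.voxel_fwe_alpha < 1.0:
            raise ValueError("voxel_fwe_alpha must be in (0, 1)")
        if self.cluster_extent_k < 1:
            raise ValueError("cluster_extent_k must be >= 1")
        if self.connectivity is None:
            self.connectivity = CLUSTER_STRUCTURE


@dataclass
class Cluster:
    label: int
    size: int
    peak_value: float
    peak_voxel: tuple
    sign: str  # "positive" | "negative"


@dataclass
class ClusterSet:
    labels: np.ndarray  # 3D integer grid, 0 = background
    clusters: list  # of Cluster

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class OverlapMap:
    fraction: np.ndarray  # in [0, 1]
    threshold_t: float
    n_subjects: int


def one_sample_tmap(maps, contrast: str = "") -> GroupStatMap:
    """Voxelwise one-sample t test of the group mean against zero.

    ``maps`` is a sequence of same-shape 3D arrays (NaN outside each
    subject's mask).  The analysis mask is the voxels finite for every
    subject; zero-variance voxels are flagged and carry a signed infinity.
    """
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    n = stack.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mask = np.isfinite(stack).all(axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_var = mask & (sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero_var] = np.sign(mean[zero_var]) * np.inf
    t[~mask] = np.nan
    return GroupStatMap(
        t=t, df=n - 1, n_subjects=n, contrast=contrast, mask=mask, zero_variance=zero_var
    )


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t values to standard-normal quantiles with matching tail area."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, np.nan)
    finite = np.isfinite(t)
    # symmetric transform; large |t| saturates to +-inf which compares fine
    out[finite] = np.sign(t[finite]) * stats.norm.isf(
        stats.t.sf(np.abs(t[finite]), df)
    )
    out[np.isposinf(t)] = np.inf
    out[np.isneginf(t)] = -np.inf
    return out


def threshold_map(gmap: GroupStatMap, spec: ThresholdSpec, mode: str = "voxel") -> ClusterSet:
    """Threshold a group t map by voxel FWE and cluster extent.

    mode="voxel" (default): a voxel survives iff it passes Bonferroni
    voxel-FWE AND lies in a cluster-forming component (|z| >= z_form) of
    size >= k; surviving voxels are then labeled into clusters.
    mode="cluster": whole cluster-forming components of size >= k survive
    when they contain at least one FWE-passing voxel.
    Positive and negative directions are processed separately.
    """
    if mode not in ("voxel", "cluster"):
        raise ValueError("mode must be 'voxel' or 'cluster'")
    m_vox = int(gmap.mask.sum())
    if m_vox == 0:
        raise ValueError("empty analysis mask")
    z = t_to_z(gmap.t, gmap.df)

    labels = np.zeros(gmap.t.shape, dtype=np.int32)
    clusters = []
    next_label = 1
    for sign, signed in (("positive", 1.0), ("negative", -1.0)):
        zs = signed * z
        ts = signed * gmap.t
        with np.errstate(invalid="ignore"):
            forming = gmap.mask & (zs >= spec.cluster_forming_z)
            p_vox = stats.t.sf(np.where(gmap.mask, ts, 0.0), gmap.df)
        fwe_pass = gmap.mask & (np.minimum(p_vox * m_vox, 1.0) <= spec.voxel_fwe_alpha)
        comp, n_comp = ndimage.label(forming, structure=spec.connectivity)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel(), minlength=n_comp + 1)
        for lab in range(1, n_comp + 1):
            if sizes[lab] < spec.cluster_extent_k:
                continue
            comp_mask = comp == lab
            if mode == "voxel":
                surv = comp_mask & fwe_pass
            else:
                surv = comp_mask if np.any(comp_mask & fwe_pass) else None
            if surv is None or not np.any(surv):
                continue
            labels[surv] = next_label
            vals = np.where(surv, ts, -np.inf)
            peak = np.unravel_index(np.argmax(vals), vals.shape)
            clusters.append(
                Cluster(
                    label=next_label,
                    size=int(surv.sum()),
                    peak_value=float(gmap.t[peak]),
                    peak_voxel=tuple(int(i) for i in peak),
                    sign=sign,
                )
            )
            next_label += 1
    return ClusterSet(labels=labels, clusters=clusters)


def estimate_cluster_extent_k(
    grid_dims: tuple,
    smoothness_fwhm_vox: float,
    cluster_forming_z: float = 3.1,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
) -> int:
    """Monte Carlo cluster-extent threshold for smooth Gaussian null fields.

    Simulates white noise smoothed to the stated FWHM (in voxels),
    standardized to unit variance, thresholded one-sided at z; returns the
    (1 - alpha) quantile of the max-cluster-size null distribution plus 1.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if any(d < 2 for d in grid_dims):
        raise ValueError("degenerate grid")
    rng = np.random.default_rng(seed)
    sigma = smoothness_fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    max_sizes = np.zeros(n_sim)
    for i in range(n_sim):
        field = rng.standard_normal(grid_dims)
        if sigma > 0:
            field = ndimage.gaussian_filter(field, sigma=sigma)
            field /= field.std()
        comp, n_comp = ndimage.label(field >= cluster_forming_z, structure=CLUSTER_STRUCTURE)
        if n_comp:
            max_sizes[i] = np.bincount(comp.ravel())[1:].max()
    q = float(np.quantile(max_sizes, 1.0 - alpha, method="higher"))
    return int(q) + 1


def compute_overlap_map(t_maps, threshold_t: float = 1.96) -> OverlapMap:
    """Fraction of subjects whose first-level t exceeds ``threshold_t``.

    One-sided in the direction of the contrast as signed; voxels outside a
    subject's mask (NaN) count as not passing for that subject.
    """
    stack = np.stack([np.asarray(m, dtype=float) for m in t_maps])
    n = stack.shape[0]
    with np.errstate(invalid="ignore"):
        passing = np.where(np.isfinite(stack), stack > threshold_t, False)
    return OverlapMap(
        fraction=passing.sum(axis=0) / n, threshold_t=threshold_t, n_subjects=n
    )
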