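"""Watershed subdivision of suprathreshold activation clusters.

Large suprathreshold clusters are split into segments, one per local peak
of the statistic map, with borders along the local minima between peaks.
The algorithm floods each cluster from its peaks in strictly decreasing
statistic order (priority queue; ties broken by lexicographic voxel index),
so the segmentation depends only on the ordering of values and is invariant
under any strictly increasing transform of the map.

Conventions: local extrema use 26-connectivity, flooding adjacency uses
18-connectivity (matching the cluster components); both are configurable.
A connected constant plateau counts as one peak, seeded at its
lexicographically smallest voxel.  A voxel adjacent to several segments is
assigned to the segment with the higher peak value (peak-value tie: the
smaller segment id).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grouplevel import ClusterSet

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _offsets(connectivity: int) -> np.ndarray:
    s = _STRUCTURES[connectivity]
    offs = np.argwhere(s) - 1
    return offs[np.any(offs != 0, axis=1)]


@dataclass
class Segment:
    label: int
    peak_voxel: tuple
    peak_value: float
    size: int
    parent_cluster: int


@dataclass
class SegmentLabelMap:
    labels: np.ndarray  # 3D int grid, 0 = background
    segments: list  # of Segment

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class SegmentStats:
    """Per-subject mean contrast value within each segment."""

    means: pd.DataFrame  # subjects x segments
    counts: pd.DataFrame  # voxels averaged per cell


def find_local_maxima(values: np.ndarray, mask: np.ndarray, connectivity: int = 26) -> list:
    """Local peaks of ``values`` restricted to ``mask``.

    A voxel (or connected equal-valued plateau) is a peak iff no in-mask
    neighbor has a greater value.  Returns ``[(voxel_index_tuple, value),
    ...]`` sorted by decreasing value then lexicographic index; each plateau
    contributes its lexicographically smallest voxel.
    """
    if not np.any(mask):
        raise ValueError("mask is empty")
    structure = _STRUCTURES[connectivity]
    fp = structure.copy()
    fp[1, 1, 1] = False
    v = np.where(mask, values, -np.inf)
    neighbor_max = ndimage.maximum_filter(v, footprint=fp, mode="constant", cval=-np.inf)
    candidates = mask & (v >= neighbor_max)

    visited = np.zeros(values.shape, dtype=bool)
    peaks = []
    for idx in np.argwhere(candidates):
        idx = tuple(idx)
        if visited[idx]:
            continue
        val = values[idx]
        # expand to the full equal-valued plateau within the mask
        seedmap = np.zeros(values.shape, dtype=bool)
        seedmap[idx] = True
        plateau = ndimage.binary_propagation(
            seedmap, mask=mask & (values == val), structure=structure
        )
        visited |= plateau
        ring = ndimage.binary_dilation(plateau, structure=structure) & mask & ~plateau
        if np.any(values[ring] > val):
            continue  # shoulder of a higher region, not a peak
        seed = tuple(min(map(tuple, np.argwhere(plateau))))
        peaks.append((seed, float(val)))
    peaks.sort(key=lambda pv: (-pv[1], pv[0]))
    return peaks


def watershed_segments(
    values: np.ndarray,
    clusters: ClusterSet | np.ndarray,
    peak_connectivity: int = 26,
    flood_connectivity: int = 18,
    min_segment_size: int = 0,
) -> SegmentLabelMap:
    """Split each cluster into one segment per local peak by flooding.

    ``clusters`` is a :class:`ClusterSet` or an integer label grid (0 =
    background).  Segments partition the suprathreshold mask exactly.
    ``min_segment_size`` optionally merges smaller segments into their
    highest-peak neighbor.
    """
    cluster_labels = clusters.labels if isinstance(clusters, ClusterSet) else clusters
    cluster_labels = np.asarray(cluster_labels)
    if not np.any(cluster_labels > 0):
        raise ValueError("empty cluster set")
    shape = values.shape
    offs = _offsets(flood_connectivity)
    labels = np.zeros(shape, dtype=np.int32)
    segments = []
    next_label = 1

    for cl in np.unique(cluster_labels[cluster_labels > 0]):
        cmask = cluster_labels == cl
        peaks = find_local_maxima(values, cmask, connectivity=peak_connectivity)
        peak_value_of = {}
        for voxel, val in peaks:
            labels[voxel] = next_label
            peak_value_of[next_label] = val
            segments.append(
                Segment(
                    label=next_label,
                    peak_voxel=voxel,
                    peak_value=val,
                    size=0,
                    parent_cluster=int(cl),
                )
            )
            next_label += 1

        # priority flood: highest value first, lexicographic tie-break
        heap = []
        counter = 0

        def push_neighbors(voxel):
            nonlocal counter
            for off in offs:
                nb = (voxel[0] + off[0], voxel[1] + off[1], voxel[2] + off[2])
                if not all(0 <= nb[d] < shape[d] for d in range(3)):
                    continue
                if cmask[nb] and labels[nb] == 0:
                    heapq.heappush(heap, (-values[nb], nb))
                    counter += 1

        for voxel, _ in peaks:
            push_neighbors(voxel)
        while heap:
            _, voxel = heapq.heappop(heap)
            if labels[voxel] != 0:
                continue
            # choose among labeled neighbors: highest peak, then smaller id
            best = None
            for off in offs:
                nb = (voxel[0] + off[0], voxel[1] + off[1], voxel[2] + off[2])
                if not all(0 <= nb[d] < shape[d] for d in range(3)):
                    continue
                lab = labels[nb]
                if lab > 0 and cmask[nb]:
                    key = (-peak_value_of[lab], lab)
                    if best is None or key < best:
                        best = key
            if best is None:  # isolated under flood connectivity; self-seed
                labels[voxel] = next_label
                peak_value_of[next_label] = float(values[voxel])
                segments.append(
                    Segment(next_label, voxel, float(values[voxel]), 0, int(cl))
                )
                next_label += 1
            else:
                labels[voxel] = best[1]
            push_neighbors(voxel)

    if min_segment_size > 0:
        labels, segments = _merge_small(values, labels, segments, offs, min_segment_size)

    for seg in segments:
        seg.size = int(np.sum(labels == seg.label))
    segments = [s for s in segments if s.size > 0]
    return SegmentLabelMap(labels=labels, segments=segments)


def _merge_small(values, labels, segments, offs, min_size):
    """Merge segments below ``min_size`` into their strongest neighbor."""
    shape = labels.shape
    by_label = {s.label: s for s in segments}
    changed = True
    while changed:
        changed = False
        sizes = {lab: int(np.sum(labels == lab)) for lab in by_label}
        for lab, size in sorted(sizes.items(), key=lambda kv: kv[1]):
            if size == 0 or size >= min_size:
                continue
            neigh = set()
            for voxel in map(tuple, np.argwhere(labels == lab)):
                for off in offs:
                    nb = tuple(voxel[d] + off[d] for d in range(3))
                    if all(0 <= nb[d] < shape[d] for d in range(3)):
                        other = labels[nb]
                        if other > 0 and other != lab:
                            neigh.add(other)
            if not neigh:
                continue
            target = min(neigh, key=lambda l: (-by_label[l].peak_value, l))
            labels[labels == lab] = target
            del by_label[lab]
            changed = True
            break
    return labels, list(by_label.values())


def extract_segment_means(seg: SegmentLabelMap, contrast_maps: dict) -> SegmentStats:
    """Mean contrast value per subject x segment.

    ``contrast_maps`` maps subject id -> 3D array (NaN outside the
    subject's mask).  A segment entirely outside a subject's mask yields a
    missing entry, not 0.
    """
    seg_labels = [s.label for s in seg.segments]
    means = {}
    counts = {}
    for sid, vol in contrast_maps.items():
        vol = np.asarray(vol, dtype=float)
        if vol.shape != seg.labels.shape:
            raise ValueError(f"grid mismatch for subject {sid!r}")
        row_m, row_c = [], []
        for lab in seg_labels:
            vals = vol[seg.labels == lab]
            vals = vals[np.isfinite(vals)]
            row_c.append(len(vals))
            row_m.append(vals.mean() if len(vals) else np.nan)
        means[sid] = row_m
        counts[sid] = row_c
    cols = [f"segment_{lab}" for lab in seg_labels]
    return SegmentStats(
        means=pd.DataFrame.from_dict(means, orient="index", columns=cols),
        counts=pd.DataFrame.from_dict(counts, orient="index", columns=cols),
    )
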