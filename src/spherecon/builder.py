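"""Streamline filtering, dense-connectome construction, and downscaling.

Streamlines shorter than an age-appropriate minimum length (5 mm neonates,
10 mm 6-month-olds, 15 mm adults) are removed to suppress tractography noise.
The dense connectome records which individual surface points are connected by
the remaining streamlines; combining its entries by parcellation node and
binarizing at a threshold of one streamline yields the N x N network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import (BinaryNetwork, DenseConnectome, StreamlineSet,
                 SurfacePointCloud, ValidationError)
from .parcellation import NodeAssignment


@dataclass
class LengthFilterReport:
    n_input: int
    n_kept: int
    n_removed: int
    threshold_mm: float

    def __post_init__(self):
        if self.n_input != self.n_kept + self.n_removed:
            raise ValidationError("n_input must equal n_kept + n_removed")


def streamline_length(polyline) -> float:
    """Arc length of a polyline: sum of Euclidean segment lengths (mm)."""
    arr = np.asarray(polyline, dtype=float)
    if arr.ndim != 2 or len(arr) < 2:
        raise ValidationError("a streamline needs at least 2 points")
    return float(np.linalg.norm(np.diff(arr, axis=0), axis=1).sum())


def filter_by_length(streamlines: StreamlineSet,
                     min_length_mm: float) -> tuple[StreamlineSet,
                                                    LengthFilterReport]:
    """Keep streamlines with length >= min_length_mm, preserving order."""
    if min_length_mm < 0:
        raise ValidationError("min_length_mm must be >= 0")
    kept = [s for s in streamlines if streamline_length(s) >= min_length_mm]
    report = LengthFilterReport(
        n_input=len(streamlines), n_kept=len(kept),
        n_removed=len(streamlines) - len(kept), threshold_mm=min_length_mm)
    return StreamlineSet(kept), report


def build_dense_connectome(streamlines: StreamlineSet,
                           surface: SurfacePointCloud,
                           endpoint_radius_mm: float = 2.0) -> DenseConnectome:
    """Detect which surface points i, j are connected by streamlines.

    Each streamline endpoint is mapped to the nearest surface point if it
    lies within ``endpoint_radius_mm``; when both endpoints map to distinct
    points i != j the count of the unordered pair (i, j) is incremented.
    Streamlines with an unmapped endpoint, or with both endpoints on the
    same surface point, contribute nothing (tallied in ``n_unmapped``).
    """
    if endpoint_radius_mm <= 0:
        raise ValidationError("endpoint_radius_mm must be > 0")
    if len(streamlines) == 0:
        return DenseConnectome(n_points=surface.n_points)
    tree = cKDTree(surface.points)
    ends = np.array([[s[0], s[-1]] for s in streamlines])  # (S, 2, 3)
    dist, idx = tree.query(ends.reshape(-1, 3))
    dist = dist.reshape(-1, 2)
    idx = idx.reshape(-1, 2)
    mapped = (dist <= endpoint_radius_mm).all(axis=1)
    counts: dict = {}
    skipped = int((~mapped).sum())
    for i, j in idx[mapped]:
        if i == j:
            skipped += 1
            continue
        key = (int(min(i, j)), int(max(i, j)))
        counts[key] = counts.get(key, 0) + 1
    return DenseConnectome(n_points=surface.n_points, counts=counts,
                           n_unmapped=skipped)


def downscale(dense: DenseConnectome,
              assignment: NodeAssignment) -> BinaryNetwork:
    """Combine dense-connectome entries into the N x N network.

    weights[a, b] sums streamline counts over dense pairs whose endpoints
    fall in nodes a != b; pairs internal to one node are discarded.  Two
    nodes are connected if at least one streamline is present (binarization
    threshold of 1 streamline).
    """
    labels = assignment.labels
    N = assignment.N
    W = np.zeros((N, N), dtype=np.int64)
    for (i, j), c in dense.counts.items():
        if i >= len(labels) or j >= len(labels):
            raise ValidationError(
                f"dense pair ({i}, {j}) not covered by the node assignment")
        a, b = labels[i], labels[j]
        if a == b:
            continue
        W[a, b] += c
        W[b, a] += c
    return BinaryNetwork(adjacency=(W >= 1).astype(np.int64), weights=W)
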