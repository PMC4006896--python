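"""Equal-area sphere parcellation.

A unit sphere is divided into N regions of equal area with a recursive zonal
scheme (two polar caps plus latitudinal collars cut into equal-area cells);
the region center points serve as node reference points.  The sphere is then
scaled to the individual brain surface and every surface point is assigned to
the closest node reference point, yielding an individual, atlas-free
parcellation into nodes of similar size.

Region boundaries are parallels of colatitude and meridian arcs chosen so the
cell areas are exactly 4*pi/N each; `SpherePartition.region_of` classifies
arbitrary unit vectors against those boundaries, which is what the Monte-Carlo
area checks exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .io import SurfacePointCloud, ValidationError


def _rotation_matrix(theta_x: float, theta_y: float, theta_z: float) -> np.ndarray:
    """Rz(tz) @ Ry(ty) @ Rx(tx) for angles in degrees."""
    return Rotation.from_euler(
        "xyz", [theta_x, theta_y, theta_z], degrees=True).as_matrix()


@dataclass
class SpherePartition:
    """N equal-area regions of the unit sphere with their center points.

    ``colat_bounds`` are the colatitude boundaries of the zones (top cap,
    collars, bottom cap) of the *unrotated* partition and ``cells_per_zone``
    the number of equal-longitude cells in each zone; together they define
    the exact region boundaries.  ``rotation`` records the applied Euler
    angles in degrees (Rz*Ry*Rx order from the unrotated base).
    """

    N: int
    centers: np.ndarray                      # (N, 3) unit vectors
    rotation: tuple = (0.0, 0.0, 0.0)
    colat_bounds: np.ndarray = field(default=None, repr=False)
    cells_per_zone: np.ndarray = field(default=None, repr=False)
    _rot: np.ndarray = field(default=None, repr=False)  # net rotation matrix

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self.N < 1:
            raise ValidationError("N must be >= 1")
        if self.centers.shape != (self.N, 3):
            raise ValidationError("centers must be (N, 3)")
        norms = np.linalg.norm(self.centers, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("centers must be unit vectors")
        if self._rot is None:
            self._rot = np.eye(3)

    def region_of(self, points: np.ndarray) -> np.ndarray:
        """Region index of each unit vector, by the exact zone boundaries."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        # classify in the partition's own (unrotated) frame
        pts = pts @ self._rot  # == (_rot.T @ p.T).T
        if self.N == 1:
            return np.zeros(len(pts), dtype=int)
        z = np.clip(pts[:, 2] / np.linalg.norm(pts, axis=1), -1.0, 1.0)
        colat = np.arccos(z)
        zone = np.clip(
            np.searchsorted(self.colat_bounds[1:-1], colat, side="right"),
            0, len(self.cells_per_zone) - 1)
        phi = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
        m = self.cells_per_zone[zone]
        cell = np.minimum((phi / (2 * np.pi) * m).astype(int), m - 1)
        offsets = np.concatenate([[0], np.cumsum(self.cells_per_zone)[:-1]])
        return offsets[zone] + cell


@dataclass
class NodeAssignment:
    """Per-surface-point node labels, one label in 0..N-1 per point."""

    labels: np.ndarray
    N: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be 1-D")
        if self.N < 1:
            raise ValidationError("N must be >= 1")
        if len(self.labels) and (self.labels.min() < 0
                                 or self.labels.max() >= self.N):
            raise ValidationError("labels out of range")

    def __len__(self) -> int:
        return len(self.labels)


def equal_area_partition(N: int) -> SpherePartition:
    """Divide the unit sphere into N regions of equal area (4*pi/N each).

    Recursive zonal scheme: a north and a south polar cap of area 4*pi/N,
    and in between latitudinal collars each cut into equal-angle longitude
    cells.  Collar boundaries are placed so every cell area is exactly
    4*pi/N.  Region centers are the spherical centroids of the cells
    (cap centers are the poles); deterministic for fixed N.
    """
    if N < 1:
        raise ValidationError("N must be >= 1")
    if N == 1:
        return SpherePartition(
            N=1, centers=np.array([[0.0, 0.0, 1.0]]),
            colat_bounds=np.array([0.0, np.pi]),
            cells_per_zone=np.array([1]))
    if N == 2:
        return SpherePartition(
            N=2, centers=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]),
            colat_bounds=np.array([0.0, np.pi / 2, np.pi]),
            cells_per_zone=np.array([1, 1]))

    cell_area = 4 * np.pi / N
    theta_cap = np.arccos(1.0 - 2.0 / N)  # polar cap of one cell area
    ideal_angle = np.sqrt(cell_area)      # square-ish cells
    n_collars = max(1, int(np.round((np.pi - 2 * theta_cap) / ideal_angle)))
    fitting = (np.pi - 2 * theta_cap) / n_collars

    # ideal (real) cell counts per collar, then round keeping the running sum
    tops = theta_cap + fitting * np.arange(n_collars + 1)
    ideal = (N / 2.0) * (np.cos(tops[:-1]) - np.cos(tops[1:]))
    m = np.zeros(n_collars, dtype=int)
    acc = 0.0
    for i in range(n_collars):
        m[i] = max(1, int(np.round(ideal[i] + acc)))
        acc += ideal[i] - m[i]
    # guard: force the exact total N - 2 onto the last collar
    m[-1] += (N - 2) - m.sum()
    if m[-1] < 1:
        raise ValidationError(f"equal-area partition failed for N={N}")

    # recompute collar boundaries so each cell has area exactly 4*pi/N
    cum = 1 + np.cumsum(m)                       # cells above each boundary
    colat_bounds = np.concatenate([
        [0.0, theta_cap],
        np.arccos(np.clip(1.0 - 2.0 * cum / N, -1.0, 1.0)),
        [np.pi]])

    cells_per_zone = np.concatenate([[1], m, [1]])
    centers = [np.array([0.0, 0.0, 1.0])]
    for i in range(n_collars):
        top, bot = colat_bounds[1 + i], colat_bounds[2 + i]
        # spherical centroid height of a band cell
        zc = 0.5 * (np.cos(top) + np.cos(bot))
        sc = np.sqrt(max(0.0, 1.0 - zc * zc))
        phis = (np.arange(m[i]) + 0.5) * 2 * np.pi / m[i]
        for phi in phis:
            centers.append(np.array([sc * np.cos(phi), sc * np.sin(phi), zc]))
    centers.append(np.array([0.0, 0.0, -1.0]))
    return SpherePartition(
        N=N, centers=np.asarray(centers),
        colat_bounds=colat_bounds, cells_per_zone=cells_per_zone)


def rotate_partition(partition: SpherePartition, theta_x: float,
                     theta_y: float, theta_z: float) -> SpherePartition:
    """Rotate the reference sphere by Rz(tz)*Ry(ty)*Rx(tx) (degrees)."""
    for a in (theta_x, theta_y, theta_z):
        if not np.isfinite(a):
            raise ValidationError("rotation angles must be finite")
    R = _rotation_matrix(theta_x, theta_y, theta_z)
    rot = tuple(np.asarray(partition.rotation, dtype=float)
                + np.array([theta_x, theta_y, theta_z]))
    centers = partition.centers @ R.T
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    return SpherePartition(
        N=partition.N, centers=centers, rotation=rot,
        colat_bounds=partition.colat_bounds,
        cells_per_zone=partition.cells_per_zone,
        _rot=R @ partition._rot)


def scale_to_surface(partition: SpherePartition,
                     surface: SurfacePointCloud) -> np.ndarray:
    """Scale the reference sphere to the brain surface.

    Reference point k = bounding-box midpoint of the surface plus the region
    center scaled per axis by the surface half-ranges.  Returns (N, 3) mm.
    """
    lo = surface.points.min(axis=0)
    hi = surface.points.max(axis=0)
    half = (hi - lo) / 2.0
    if np.any(half <= 0):
        raise ValidationError(
            "degenerate surface: zero extent on axis "
            f"{int(np.argmin(half))}")
    return (lo + hi) / 2.0 + partition.centers * half


def assign_nodes(surface: SurfacePointCloud,
                 scaled_refs: np.ndarray) -> NodeAssignment:
    """Assign every surface point to the closest node reference point.

    Ties are broken toward the lowest node index.  Nodes may end up with no
    surface points; they become isolated in the downscaled network, which is
    exactly what drives the optimal-N selection.
    """
    refs = np.asarray(scaled_refs, dtype=float)
    if refs.ndim != 2 or refs.shape[1] != 3 or len(refs) < 1:
        raise ValidationError("scaled_refs must be a non-empty (N, 3) array")
    labels = np.empty(len(surface.points), dtype=int)
    # chunked exhaustive scan; argmin returns the first (lowest) index on ties
    chunk = max(1, int(2e6 // max(1, len(refs))))
    for start in range(0, len(labels), chunk):
        d = cdist(surface.points[start:start + chunk], refs)
        labels[start:start + chunk] = np.argmin(d, axis=1)
    return NodeAssignment(labels=labels, N=len(refs))
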