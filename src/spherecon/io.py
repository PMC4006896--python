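"""Domain types and plain-text readers/writers.

All coordinates are millimetres in a right-handed scanner frame; no orientation
metadata is interpreted (the framework deliberately de-emphasizes anatomical
location).  All node and point indices in files are 0-based.  Adjacency
matrices are CSV integer matrices without a header row by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class FormatError(ValueError):
    """A file could not be parsed (malformed line, wrong column count)."""


class ValidationError(ValueError):
    """Parsed data violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SurfacePointCloud:
    """Unlabeled 3-D points (mm) sampled on the subcortical surface.

    The point id is the 0-based position in ``points``.  These are the points
    *i*, *j* of the dense connectome.
    """

    points: np.ndarray  # (M, 3) float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("surface points must be an (M, 3) array")
        if len(self.points) < 4:
            raise ValidationError(
                f"surface needs at least 4 points, got {len(self.points)}")
        if not np.isfinite(self.points).all():
            raise ValidationError("surface coordinates must be finite")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class StreamlineSet:
    """Whole-brain tractography streamlines, same mm frame as the surface."""

    streamlines: list  # list of (k_i, 3) float arrays, k_i >= 2

    def __post_init__(self):
        cleaned = []
        for s_idx, line in enumerate(self.streamlines):
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(
                    f"streamline {s_idx} is not a sequence of 3-D points")
            if len(arr) < 2:
                raise ValidationError(
                    f"streamline {s_idx} has fewer than 2 points")
            if not np.isfinite(arr).all():
                raise ValidationError(
                    f"streamline {s_idx} has non-finite coordinates")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]


@dataclass
class DenseConnectome:
    """All-to-all connectivity among individual surface points.

    ``counts`` maps unordered surface-point pairs (i, j), stored with i < j,
    to the number of streamlines connecting them.  Self pairs are excluded.
    """

    n_points: int
    counts: dict = field(default_factory=dict)  # (i, j) i<j -> count >= 1
    n_unmapped: int = 0  # streamlines skipped because an endpoint did not map

    def __post_init__(self):
        for (i, j), c in self.counts.items():
            if not (0 <= i < j < self.n_points):
                raise ValidationError(f"invalid dense pair ({i}, {j})")
            if c < 1:
                raise ValidationError(f"dense pair ({i}, {j}) has count {c}")

    @property
    def n_edges(self) -> int:
        return len(self.counts)


@dataclass(eq=False)
class BinaryNetwork:
    """Symmetric N x N 0/1 adjacency with zero diagonal.

    Optional streamline-count weights satisfy adjacency[i, j] == 1 iff
    weights[i, j] >= 1; all downstream analysis uses the binarized matrix.
    """

    adjacency: np.ndarray
    weights: np.ndarray | None = None
    node_coords: np.ndarray | None = None

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValidationError("adjacency must have zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        self.adjacency = A.astype(np.int64)
        if self.weights is not None:
            W = np.asarray(self.weights)
            if W.shape != A.shape:
                raise ValidationError("weights shape must match adjacency")
            if not np.array_equal(W, W.T):
                raise ValidationError("weights must be symmetric")
            if np.any(W < 0):
                raise ValidationError("weights must be non-negative")
            if not np.array_equal((W >= 1).astype(int), self.adjacency):
                raise ValidationError(
                    "adjacency[i,j] = 1 must hold exactly where weights >= 1")
            self.weights = W.astype(np.int64)

    @property
    def N(self) -> int:
        return self.adjacency.shape[0]

    @property
    def nnz(self) -> int:
        """Nonzero entries of the full symmetric matrix (= 2 x edge count)."""
        return int(np.count_nonzero(self.adjacency))

    @property
    def n_edges(self) -> int:
        return self.nnz // 2

    def effective_weights(self) -> np.ndarray:
        return self.weights if self.weights is not None else self.adjacency

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryNetwork):
            return NotImplemented
        return (np.array_equal(self.adjacency, other.adjacency)
                and np.array_equal(self.effective_weights(),
                                   other.effective_weights()))


@dataclass
class RunConfig:
    """Collected pipeline parameters.

    ``min_streamline_length_mm`` follows the age-dependent protocol (5 mm for
    neonates, 10 mm for 6-month-olds, 15 mm for adults); the adult value is
    the default.  SA controls mirror the best-of-100-runs alignment protocol,
    and the randomization controls the 100-network / 1000-rewires-per-edge
    normalization ensemble.
    """

    node_counts_to_try: list = field(default_factory=lambda: [
        10, 50, 90, 95, 100, 105, 110, 150, 300, 500, 1000, 3000])
    min_streamline_length_mm: float = 15.0
    endpoint_radius_mm: float = 2.0
    sa_restarts: int = 100
    sa_iterations: int = 200
    cooling_factor: float | None = None  # None: anneal to the floor in-run
    random_seed: int = 0
    n_random_networks: int = 100
    rewires_per_edge: int = 1000

    def __post_init__(self):
        counts = list(self.node_counts_to_try)
        if not counts or any(n < 1 for n in counts):
            raise ValidationError("node_counts_to_try must be positive")
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValidationError("node_counts_to_try must be strictly increasing")
        if self.min_streamline_length_mm < 0:
            raise ValidationError("min_streamline_length_mm must be >= 0")
        if self.endpoint_radius_mm <= 0:
            raise ValidationError("endpoint_radius_mm must be > 0")
        if self.cooling_factor is not None and not (0 < self.cooling_factor < 1):
            raise ValidationError("cooling_factor must be in (0, 1)")
        for name in ("sa_restarts", "sa_iterations", "n_random_networks",
                     "rewires_per_edge"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=list)


# ---------------------------------------------------------------------------
# surface I/O
# ---------------------------------------------------------------------------

def read_surface(path) -> SurfacePointCloud:
    """Read a whitespace/TSV file of x y z coordinates (mm), '#' comments."""
    pts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 coordinates, "
                    f"got {len(parts)}")
            try:
                pts.append([float(v) for v in parts])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric coordinate") from exc
    return SurfacePointCloud(np.asarray(pts, dtype=float).reshape(-1, 3))


def write_surface(surface: SurfacePointCloud, path) -> None:
    np.savetxt(path, surface.points, fmt="%.10g", delimiter="\t",
               header="x\ty\tz", comments="# ")


# ---------------------------------------------------------------------------
# streamline I/O
# ---------------------------------------------------------------------------

_STREAM_COLUMNS = ("streamline_id", "point_order", "x", "y", "z")


def read_streamlines(path, dialect: str = "native-tsv") -> StreamlineSet:
    """Read streamlines.

    The native dialect is a TSV with columns streamline_id, point_order, x,
    y, z; polylines are grouped by id and ordered by point_order.  ``trk``
    reads a TrackVis file through nibabel (optional dependency).
    """
    if dialect == "trk":
        return _read_trk(path)
    if dialect != "native-tsv":
        raise ValueError(f"unknown streamline dialect: {dialect!r}")

    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        return StreamlineSet([])
    lines = []
    for sid, grp in df.groupby("streamline_id", sort=True):
        if len(grp) < 2:
            raise ValidationError(
                f"{path}: streamline {sid} has fewer than 2 points")
        grp = grp.sort_values("point_order")
        lines.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
    return StreamlineSet(lines)


def _read_trk(path) -> StreamlineSet:
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading TRK files requires nibabel") from exc
    trk = nib.streamlines.load(str(path))
    return StreamlineSet([np.asarray(s, dtype=float) for s in trk.streamlines])


def write_streamlines(streamlines: StreamlineSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_STREAM_COLUMNS) + "\n")
        for sid, line in enumerate(streamlines):
            for order, (x, y, z) in enumerate(line):
                fh.write(f"{sid}\t{order}\t{x:.10g}\t{y:.10g}\t{z:.10g}\n")


# ---------------------------------------------------------------------------
# adjacency I/O
# ---------------------------------------------------------------------------

def read_adjacency(path) -> BinaryNetwork:
    """Read an N x N CSV of non-negative integer streamline counts.

    Entries > 1 are kept as weights; the adjacency is the matrix binarized
    at a threshold of 1 streamline.
    """
    mat = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=np.int64))
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise FormatError(f"{path}: matrix is not square: {mat.shape}")
    if np.any(mat < 0):
        raise ValidationError(f"{path}: negative entries")
    if not np.array_equal(mat, mat.T):
        raise ValidationError(f"{path}: matrix is not symmetric")
    if np.any(np.diag(mat) != 0):
        raise ValidationError(f"{path}: nonzero diagonal")
    adjacency = (mat >= 1).astype(np.int64)
    weights = mat if mat.max(initial=0) > 1 else None
    return BinaryNetwork(adjacency=adjacency, weights=weights)


def write_adjacency(net: BinaryNetwork, path) -> None:
    """Write the streamline-count matrix (or the 0/1 adjacency) as CSV."""
    np.savetxt(path, net.effective_weights(), fmt="%d", delimiter=",")


def read_config(path) -> RunConfig:
    return RunConfig.from_json(path)
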