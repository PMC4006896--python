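"""Synthetic brain phantoms with known ground-truth network structure.

Real cohorts for this pipeline are diffusion-MRI scans; the phantom module
replaces them with fully synthetic subjects — an ellipsoidal "brain" surface,
a modular (planted-partition) ground-truth network at a chosen node count,
and streamlines whose endpoints land in the correct nodes — so every pipeline
stage can be exercised against a known answer.  With zero endpoint jitter the
construction round-trips exactly: building the dense connectome from the
synthesized streamlines and downscaling it recovers the planted adjacency.

Default study conditions mirror the cohorts the pipeline targets: brain-scale
ellipsoid half-axes of (60, 80, 55) mm, four subjects per group, a 95-node
working resolution downstream, and streamline lengths that clear the adult
15 mm threshold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import build_dense_connectome, downscale
from .io import (BinaryNetwork, StreamlineSet, SurfacePointCloud,
                 ValidationError)
from .parcellation import (NodeAssignment, assign_nodes, equal_area_partition,
                           scale_to_surface)


class GenerationError(RuntimeError):
    """A phantom could not be generated under the requested spec."""


@dataclass
class PhantomSpec:
    """Recipe for one synthetic subject."""

    surface_shape: tuple = (60.0, 80.0, 55.0)  # ellipsoid half-axes, mm
    n_surface_points: int = 2000
    n_true: int = 20          # ground-truth node count
    n_modules: int = 4
    p_in: float = 0.7         # intra-module edge probability
    p_out: float = 0.1        # inter-module edge probability
    streamlines_per_edge: int = 3
    endpoint_jitter_mm: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if isinstance(self.surface_shape, str):
            if self.surface_shape != "sphere":
                raise ValidationError(
                    "surface_shape must be 'sphere' or three half-axes")
            self.surface_shape = (70.0, 70.0, 70.0)
        self.surface_shape = tuple(float(a) for a in self.surface_shape)
        if any(a <= 0 for a in self.surface_shape):
            raise ValidationError("half-axes must be positive")
        for p in (self.p_in, self.p_out):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must be in [0, 1]")
        if self.n_true < self.n_modules:
            raise ValidationError("n_true must be >= n_modules")
        if self.n_surface_points < 4 or self.streamlines_per_edge < 1:
            raise ValidationError("counts must be positive")
        if self.endpoint_jitter_mm < 0:
            raise ValidationError("jitter must be >= 0")


@dataclass
class PhantomSubject:
    """One synthetic subject: its network, optional full imaging-like data,
    and the bookkeeping needed to verify recovery."""

    network: BinaryNetwork
    permutation: np.ndarray | None = None   # applied node permutation
    surface: SurfacePointCloud | None = None
    streamlines: StreamlineSet | None = None
    assignment: NodeAssignment | None = None
    ground_truth: BinaryNetwork | None = None
    flipped_edges: list = field(default_factory=list)


def make_surface(spec: PhantomSpec, seed=None) -> SurfacePointCloud:
    """Sample points quasi-uniformly (area-weighted) on the ellipsoid.

    Directions are drawn uniformly on the unit sphere and accepted with
    probability proportional to the local surface-area element of the
    ellipsoid, so the cloud is uniform per unit area rather than per unit
    solid angle.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    a, b, c = spec.surface_shape
    w_max = max(b * c, a * c, a * b)
    pts = []
    while len(pts) < spec.n_surface_points:
        u = rng.normal(size=(spec.n_surface_points, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        w = np.sqrt((b * c * u[:, 0]) ** 2 + (a * c * u[:, 1]) ** 2
                    + (a * b * u[:, 2]) ** 2) / w_max
        keep = rng.random(len(u)) < w
        pts.extend(u[keep] * np.array([a, b, c]))
    return SurfacePointCloud(np.asarray(pts[: spec.n_surface_points]))


def make_ground_truth_network(n_true: int, n_modules: int, p_in: float,
                              p_out: float, seed=None,
                              ensure_connected: bool = True) -> BinaryNetwork:
    """Planted-partition (stochastic block model) ground-truth network.

    Nodes are split into ``n_modules`` contiguous blocks; edges appear with
    probability ``p_in`` within a block and ``p_out`` between blocks.  If the
    draw is disconnected and ``ensure_connected`` is set, the missing links
    of a module-spanning ring over all nodes are added and the repair is
    flagged on the returned network (attribute ``bridge_added``).
    """
    if n_true < n_modules or n_modules < 1:
        raise ValidationError("need n_true >= n_modules >= 1")
    rng = np.random.default_rng(seed)
    module = (np.arange(n_true) * n_modules) // n_true
    same = module[:, None] == module[None, :]
    prob = np.where(same, p_in, p_out)
    upper = np.triu(rng.random((n_true, n_true)) < prob, k=1)
    A = (upper | upper.T).astype(np.int64)

    bridge_added = False
    from scipy.sparse.csgraph import connected_components as cs
    from scipy.sparse import csr_matrix
    n_comp, _ = cs(csr_matrix(A), directed=False)
    if n_comp > 1 and ensure_connected:
        for i in range(n_true):
            j = (i + 1) % n_true
            if i != j:
                A[i, j] = A[j, i] = 1
        bridge_added = True
    net = BinaryNetwork(adjacency=A)
    net.bridge_added = bridge_added
    net.modules = module
    return net


def synthesize_streamlines(ground_truth: BinaryNetwork,
                           surface: SurfacePointCloud,
                           assignment: NodeAssignment,
                           streamlines_per_edge: int = 3,
                           jitter_mm: float = 0.0, seed=None,
                           interior_pull: float = 0.25) -> StreamlineSet:
    """Emit streamlines realizing the ground-truth network on a surface.

    For every ground-truth edge (a, b), ``streamlines_per_edge`` polylines
    are created whose endpoints are (jittered) random surface points of
    nodes a and b.  Each polyline passes through an interior waypoint pulled
    toward the surface centroid, so its arc length is on the order of the
    brain size and clears any realistic length threshold.  With zero jitter
    the dense-connectome build followed by downscaling recovers the planted
    adjacency exactly.
    """
    if len(assignment) != surface.n_points:
        raise ValidationError("assignment must cover the surface")
    rng = np.random.default_rng(seed)
    members = [np.flatnonzero(assignment.labels == k)
               for k in range(assignment.N)]
    centroid = surface.points.mean(axis=0)
    lines = []
    ii, jj = np.triu_indices(ground_truth.N, k=1)
    for a, b in zip(ii, jj):
        if not ground_truth.adjacency[a, b]:
            continue
        for node in (a, b):
            if len(members[node]) == 0:
                raise GenerationError(
                    f"node {node} owns no surface points; cannot place "
                    "streamline endpoints")
        for _ in range(streamlines_per_edge):
            p1 = surface.points[rng.choice(members[a])]
            p2 = surface.points[rng.choice(members[b])]
            if jitter_mm > 0:
                p1 = p1 + rng.normal(scale=jitter_mm, size=3)
                p2 = p2 + rng.normal(scale=jitter_mm, size=3)
            mid = centroid + interior_pull * ((p1 + p2) / 2.0 - centroid)
            lines.append(np.array([p1, mid, p2]))
    return StreamlineSet(lines)


def _flip_edges(adjacency: np.ndarray, flip_rate: float,
                rng: np.random.Generator):
    """Flip a Bernoulli(flip_rate) subset of lower-triangle entries."""
    N = adjacency.shape[0]
    A = adjacency.copy()
    ii, jj = np.tril_indices(N, k=-1)
    flip = rng.random(len(ii)) < flip_rate
    flipped = []
    for i, j in zip(ii[flip], jj[flip]):
        A[i, j] = A[j, i] = 1 - A[i, j]
        flipped.append((int(i), int(j)))
    return A, flipped


def make_cohort(ground_truth: BinaryNetwork, n_subjects: int = 4,
                edge_flip_rate: float = 0.05, permute_nodes: bool = True,
                seed=None) -> list:
    """Cohort of subjects derived from one ground-truth network.

    Each subject flips a fraction ``edge_flip_rate`` of the lower-triangle
    entries (within-group variability) and, when ``permute_nodes`` is set,
    applies a recorded random node permutation (each brain arrives in its
    own node order, the premise network alignment must undo).
    """
    if n_subjects < 2:
        raise ValidationError("a cohort needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        A, flipped = _flip_edges(ground_truth.adjacency, edge_flip_rate, rng)
        perm = None
        if permute_nodes:
            perm = rng.permutation(ground_truth.N)
            A = A[np.ix_(perm, perm)]
        subjects.append(PhantomSubject(
            network=BinaryNetwork(adjacency=A), permutation=perm,
            ground_truth=ground_truth, flipped_edges=flipped))
    return subjects


def default_contrast_edges(n_edges: int = 6) -> list:
    """A connected path of ``n_edges`` edges over nodes 0..n_edges."""
    return [(i, i + 1) for i in range(n_edges)]


def make_group_difference_cohort(ground_truth: BinaryNetwork,
                                 n_per_group: int = 10,
                                 edge_flip_rate: float = 0.05,
                                 contrast_edges: list | None = None,
                                 seed=None) -> tuple:
    """Two groups sharing a ground truth except for a planted contrast.

    Group A subjects are noisy copies of the ground truth; group B subjects
    are noisy copies of the ground truth with every edge in
    ``contrast_edges`` toggled (default: a connected 6-edge path), giving a
    connected component of group difference for power testing.
    """
    if contrast_edges is None:
        contrast_edges = default_contrast_edges()
    rng = np.random.default_rng(seed)
    base_b = ground_truth.adjacency.copy()
    for i, j in contrast_edges:
        base_b[i, j] = base_b[j, i] = 1 - base_b[i, j]
    group_a, group_b = [], []
    for _ in range(n_per_group):
        A, _ = _flip_edges(ground_truth.adjacency, edge_flip_rate, rng)
        group_a.append(BinaryNetwork(adjacency=A))
        B, _ = _flip_edges(base_b, edge_flip_rate, rng)
        group_b.append(BinaryNetwork(adjacency=B))
    return group_a, group_b, contrast_edges


def make_subject(spec: PhantomSpec, seed=None) -> PhantomSubject:
    """Full synthetic subject: surface, ground-truth network, streamlines.

    The surface is parcellated at the spec's ground-truth node count and
    streamlines are synthesized so that rebuilding the connectome from them
    recovers the planted network (exactly, when jitter is zero).
    """
    master = np.random.SeedSequence(spec.seed if seed is None else seed)
    s_surface, s_net, s_lines = master.spawn(3)
    surface = make_surface(spec, seed=s_surface)
    part = equal_area_partition(spec.n_true)
    refs = scale_to_surface(part, surface)
    assignment = assign_nodes(surface, refs)
    truth = make_ground_truth_network(spec.n_true, spec.n_modules, spec.p_in,
                                      spec.p_out, seed=s_net)
    lines = synthesize_streamlines(truth, surface, assignment,
                                   spec.streamlines_per_edge,
                                   spec.endpoint_jitter_mm, seed=s_lines)
    return PhantomSubject(network=truth, surface=surface, streamlines=lines,
                          assignment=assignment, ground_truth=truth)


def rebuild_network(subject: PhantomSubject,
                    endpoint_radius_mm: float = 2.0) -> BinaryNetwork:
    """Run the construction pipeline on a full phantom subject."""
    dense = build_dense_connectome(subject.streamlines, subject.surface,
                                   endpoint_radius_mm)
    return downscale(dense, subject.assignment)
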