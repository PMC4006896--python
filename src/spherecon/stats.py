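"""Edge-wise two-group statistics on aligned cohorts.

Once all subjects are aligned to a common reference, each of the N(N-1)/2
connections can be contrasted between two groups with a two-sample t-test.
Multiple comparisons are handled either by Benjamini-Hochberg FDR over the
edge-wise p-values, or by the network-based statistic (NBS): threshold the
edge-wise t-statistics, find the connected components they form, and assign
each observed component a corrected p-value from the permutation null
distribution of the maximal component size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cs_components
from statsmodels.stats.multitest import multipletests

from .io import BinaryNetwork, ValidationError
from .alignment import SumNetwork, lower_triangle

#: finite stand-in for an infinite t on zero-variance edges with unequal means
T_SENTINEL = 1e12


@dataclass
class EdgewiseTestResult:
    """Per-edge two-sample t statistics over the N(N-1)/2 lower-triangle
    edges, in ``np.tril_indices(N, -1)`` order."""

    t_stat: np.ndarray
    p_value: np.ndarray
    n_a: int
    n_b: int
    N: int

    def __post_init__(self):
        m = self.N * (self.N - 1) // 2
        if len(self.t_stat) != m or len(self.p_value) != m:
            raise ValidationError(f"expected {m} edges for N={self.N}")


@dataclass
class NBSResult:
    t_threshold: float
    observed_components: list      # list of (edge list [(i, j), ...], size)
    null_max_sizes: np.ndarray     # K values
    corrected_p: np.ndarray        # one per observed component

    @property
    def significant(self):
        return [comp for comp, p in zip(self.observed_components,
                                        self.corrected_p) if p <= 0.05]


def _edge_matrix(group: list) -> np.ndarray:
    """Stack each subject's lower-triangle edge values into (S, E)."""
    rows = []
    for net in group:
        if isinstance(net, BinaryNetwork):
            rows.append(lower_triangle(net.adjacency).astype(float))
        elif isinstance(net, SumNetwork):
            rows.append(lower_triangle(net.counts).astype(float))
        else:
            rows.append(lower_triangle(np.asarray(net)).astype(float))
    X = np.vstack(rows)
    return X


def _pooled_t(XA: np.ndarray, XB: np.ndarray):
    """Vectorized pooled-variance two-sample t per column."""
    nA, nB = len(XA), len(XB)
    mA, mB = XA.mean(axis=0), XB.mean(axis=0)
    vA = XA.var(axis=0, ddof=1)
    vB = XB.var(axis=0, ddof=1)
    df = nA + nB - 2
    sp2 = ((nA - 1) * vA + (nB - 1) * vB) / df
    denom = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    diff = mA - mB
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    degenerate = denom == 0
    t[degenerate & (diff == 0)] = 0.0
    t[degenerate & (diff > 0)] = T_SENTINEL
    t[degenerate & (diff < 0)] = -T_SENTINEL
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p[degenerate & (diff == 0)] = 1.0
    return t, p


def edgewise_ttest(group_a: list, group_b: list) -> EdgewiseTestResult:
    """Two-sample pooled-variance t-test at each connection independently.

    Edges with zero variance in both groups get t = 0, p = 1 when the group
    means agree, and a signed large sentinel (p ~ 0) when they differ.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 subjects")
    XA, XB = _edge_matrix(group_a), _edge_matrix(group_b)
    if XA.shape[1] != XB.shape[1]:
        raise ValidationError("groups have different network sizes")
    t, p = _pooled_t(XA, XB)
    N = _infer_n(XA.shape[1])
    return EdgewiseTestResult(t_stat=t, p_value=p, n_a=len(XA), n_b=len(XB),
                              N=N)


def _infer_n(n_edges: int) -> int:
    N = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if N * (N - 1) // 2 != n_edges:
        raise ValidationError(f"{n_edges} is not a triangular number")
    return N


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up at level q; returns the discovery mask."""
    p = np.asarray(p_values, dtype=float)
    if not (0 < q < 1):
        raise ValidationError("q must be in (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _component_sizes(supra: np.ndarray, N: int, tril_idx):
    """Connected components of the suprathreshold edge graph.

    Returns (labels per suprathreshold edge, sizes in edge count).
    """
    rows = tril_idx[0][supra]
    cols = tril_idx[1][supra]
    if len(rows) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    data = np.ones(len(rows))
    adj = coo_matrix((data, (rows, cols)), shape=(N, N))
    _, node_labels = _cs_components(adj.tocsr(), directed=False)
    edge_labels = node_labels[rows]
    # compact labels to the components that actually carry edges
    uniq, edge_labels = np.unique(edge_labels, return_inverse=True)
    sizes = np.bincount(edge_labels)
    return edge_labels, sizes


def nbs(group_a: list, group_b: list, t_threshold: float, K: int = 1000,
        seed=None) -> NBSResult:
    """Network-based statistic for a two-group edge-wise contrast.

    1) a two-sample t-test at each edge; 2) suprathreshold edges are those
    with |t| >= t_threshold; 3) connected components of the suprathreshold
    graph are the observed components, measured in edge count; 4) group
    labels are randomly permuted K times and the maximal component size
    stored, giving the null distribution from which each observed component
    receives a corrected p-value (1 + #{null >= size}) / (K + 1).
    """
    if t_threshold <= 0:
        raise ValidationError("t_threshold must be > 0")
    if K < 1:
        raise ValidationError("K must be >= 1")
    XA, XB = _edge_matrix(group_a), _edge_matrix(group_b)
    if XA.shape[1] != XB.shape[1]:
        raise ValidationError("groups have different network sizes")
    if len(XA) < 2 or len(XB) < 2:
        raise ValidationError("each group needs at least 2 subjects")
    N = _infer_n(XA.shape[1])
    tril_idx = np.tril_indices(N, k=-1)
    nA = len(XA)
    X = np.vstack([XA, XB])

    t_obs, _ = _pooled_t(XA, XB)
    supra = np.abs(t_obs) >= t_threshold
    edge_labels, sizes = _component_sizes(supra, N, tril_idx)
    supra_pairs = list(zip(tril_idx[0][supra], tril_idx[1][supra]))
    observed = []
    for cid, size in enumerate(sizes):
        edges = [(int(i), int(j)) for (i, j), lab in
                 zip(supra_pairs, edge_labels) if lab == cid]
        observed.append((edges, int(size)))

    rng = np.random.default_rng(seed)
    null_max = np.zeros(K, dtype=int)
    idx = np.arange(len(X))
    for k in range(K):
        perm = rng.permutation(idx)
        t_k, _ = _pooled_t(X[perm[:nA]], X[perm[nA:]])
        _, sizes_k = _component_sizes(np.abs(t_k) >= t_threshold, N, tril_idx)
        null_max[k] = sizes_k.max() if len(sizes_k) else 0

    corrected = np.array([
        (1 + int((null_max >= size).sum())) / (K + 1)
        for _, size in observed])
    return NBSResult(t_threshold=t_threshold, observed_components=observed,
                     null_max_sizes=null_max, corrected_p=corrected)
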