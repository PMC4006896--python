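"""Connected components, optimal node count, and normalized global metrics.

Because raw network measures depend on edge count, edge distribution, and
component size, the clustering coefficient C and characteristic path length L
are normalized by their means over an ensemble of degree-preserving random
networks (Maslov-Sneppen double-edge swaps): Cr = C/C_rand, Lr = L/L_rand,
and the small-world index swi = Cr/Lr.  Modularity Q is maximized over
seeded Louvain restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cs_components

from .builder import downscale
from .io import BinaryNetwork, DenseConnectome, SurfacePointCloud, ValidationError
from .parcellation import assign_nodes, equal_area_partition, scale_to_surface


class DisconnectedGraphError(ValueError):
    """Raised when a metric requiring a connected graph gets a disconnected
    one; restrict to the giant component first."""


@dataclass
class ComponentDecomposition:
    """Undirected connected components with deterministic labeling:
    component 0 contains the lowest-indexed node, and so on."""

    n_components: int
    membership: np.ndarray  # node -> component id
    giant_size: int

    def component_nodes(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.membership == cid)

    @property
    def giant_component(self) -> np.ndarray:
        sizes = np.bincount(self.membership)
        return np.flatnonzero(self.membership == int(np.argmax(sizes)))


@dataclass
class GlobalMetrics:
    C: float
    L: float
    Q: float
    C_rand: float
    L_rand: float
    Cr: float
    Lr: float
    swi: float
    C_rand_samples: np.ndarray = field(default=None, repr=False)
    L_rand_samples: np.ndarray = field(default=None, repr=False)


def connected_components(net: BinaryNetwork) -> ComponentDecomposition:
    """Enumerate all groups of interconnected nodes."""
    n, raw = _cs_components(csr_matrix(net.adjacency), directed=False)
    # relabel so ids follow the order of first appearance by node index
    order = {}
    membership = np.empty_like(raw)
    for node, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order)
        membership[node] = order[lab]
    sizes = np.bincount(membership)
    return ComponentDecomposition(n_components=int(n), membership=membership,
                                  giant_size=int(sizes.max()))


def network_at_n(dense: DenseConnectome, surface: SurfacePointCloud,
                 n_nodes: int) -> BinaryNetwork:
    """Parcellate the surface at N nodes and downscale the dense connectome."""
    part = equal_area_partition(n_nodes)
    refs = scale_to_surface(part, surface)
    assignment = assign_nodes(surface, refs)
    net = downscale(dense, assignment)
    net.node_coords = refs
    return net


def find_optimal_N(dense_per_subject: list, surfaces: list,
                   candidates: list) -> int | None:
    """Finest parcellation that still interconnects the whole brain.

    Returns the highest candidate N at which every subject's N-node network
    forms exactly one connected component spanning all N nodes (no node
    isolated), or None if no candidate qualifies.
    """
    if not candidates:
        raise ValidationError("candidates must be non-empty")
    if len(dense_per_subject) != len(surfaces):
        raise ValidationError("need one surface per dense connectome")
    for n_nodes in sorted(candidates, reverse=True):
        ok = True
        for dense, surf in zip(dense_per_subject, surfaces):
            comp = connected_components(network_at_n(dense, surf, n_nodes))
            if comp.n_components != 1 or comp.giant_size != n_nodes:
                ok = False
                break
        if ok:
            return n_nodes
    return None


def _path_length(G: nx.Graph) -> float:
    """Mean shortest-path length; giant component if disconnected."""
    if not nx.is_connected(G):
        nodes = max(nx.connected_components(G), key=len)
        G = G.subgraph(nodes)
    if G.number_of_nodes() < 2:
        return 0.0
    return nx.average_shortest_path_length(G)


def _max_modularity(G: nx.Graph, n_restarts: int, rng: np.random.Generator) -> float:
    best = -np.inf
    for _ in range(n_restarts):
        seed = int(rng.integers(2**31 - 1))
        comms = nx.community.louvain_communities(G, seed=seed)
        best = max(best, nx.community.modularity(G, comms))
    return float(best)


def randomize_degree_preserving(net: BinaryNetwork, rewires_per_edge: int,
                                seed) -> BinaryNetwork:
    """One Maslov-Sneppen randomization: rewires_per_edge * |E| accepted
    double-edge swaps.  The degree sequence is preserved exactly."""
    G = nx.from_numpy_array(net.adjacency)
    n_edges = G.number_of_edges()
    nswap = rewires_per_edge * n_edges
    if n_edges >= 2:
        try:
            nx.double_edge_swap(G, nswap=nswap, max_tries=100 * nswap + 100,
                                seed=np.random.RandomState(seed))
        except nx.NetworkXAlgorithmError:
            pass  # too few swappable pairs (e.g. complete graph): keep as is
    A = nx.to_numpy_array(G, nodelist=range(net.N), dtype=np.int64)
    return BinaryNetwork(adjacency=A)


def global_metrics(net: BinaryNetwork, n_random: int = 100,
                   rewires_per_edge: int = 1000, seed=None,
                   n_louvain_restarts: int = 20) -> GlobalMetrics:
    """Normalized global metrics of a connected binary network.

    C is the mean local clustering coefficient (0 for nodes of degree < 2),
    L the mean shortest-path length over all node pairs, Q the best Louvain
    modularity over ``n_louvain_restarts`` seeded restarts.  C_rand and
    L_rand are means over ``n_random`` degree-preserving randomizations with
    ``rewires_per_edge`` accepted swaps per edge each.
    """
    if n_random < 1:
        raise ValidationError("n_random must be >= 1")
    comp = connected_components(net)
    if comp.n_components != 1:
        raise DisconnectedGraphError(
            f"graph has {comp.n_components} components; compute metrics on "
            "the giant component (see giant_subnetwork)")
    rng = np.random.default_rng(seed)
    G = nx.from_numpy_array(net.adjacency)
    C = float(nx.average_clustering(G))
    L = float(nx.average_shortest_path_length(G))
    Q = _max_modularity(G, n_louvain_restarts, rng)

    Cs = np.empty(n_random)
    Ls = np.empty(n_random)
    for k in range(n_random):
        rnd = randomize_degree_preserving(
            net, rewires_per_edge, int(rng.integers(2**31 - 1)))
        Gr = nx.from_numpy_array(rnd.adjacency)
        Cs[k] = nx.average_clustering(Gr)
        Ls[k] = _path_length(Gr)
    C_rand, L_rand = float(Cs.mean()), float(Ls.mean())
    Cr = C / C_rand if C_rand > 0 else np.inf
    Lr = L / L_rand if L_rand > 0 else np.inf
    return GlobalMetrics(C=C, L=L, Q=Q, C_rand=C_rand, L_rand=L_rand,
                         Cr=Cr, Lr=Lr, swi=Cr / Lr,
                         C_rand_samples=Cs, L_rand_samples=Ls)


def giant_subnetwork(net: BinaryNetwork) -> BinaryNetwork:
    """Restrict a network to its giant component."""
    nodes = connected_components(net).giant_component
    W = net.effective_weights()[np.ix_(nodes, nodes)]
    sub = BinaryNetwork(adjacency=net.adjacency[np.ix_(nodes, nodes)],
                        weights=W if net.weights is not None else None)
    if net.node_coords is not None:
        sub.node_coords = net.node_coords[nodes]
    return sub
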