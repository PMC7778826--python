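"""Patient-similarity complex networks and their node-level statistics.

Each record to classify gets three weighted undirected graphs over the
preprocessed training records:

* CN1 — the query plus every training record,
* CN2 — the query plus positive-labelled training records only,
* CN3 — the query plus negative-labelled training records only.

An edge joins two records whose Euclidean distance falls strictly below a
threshold tau = tau_factor x mean pairwise distance; its weight is the
distance divided by the maximum pairwise distance, hence in [0, 1].  Weights
are therefore *dissimilarities*: path-based statistics (closeness,
betweenness, minimum shortest path) use them as lengths, while count-based
statistics (degree, clustering, two-hop, eigenvector) use the binary
adjacency.  Large networks are partitioned into modularity communities and a
node's metrics are computed on its community's induced subgraph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csgraph
from scipy.spatial.distance import pdist, squareform

from .table import FeatureTable

#: sentinel shortest-path length of an isolated node
UNREACHABLE = math.inf

DEFAULT_TAU_FACTOR = 0.7
DEFAULT_COMMUNITY_SIZE_LIMIT = 2000


@dataclass
class ComplexNetwork:
    """Weighted undirected patient-similarity graph."""

    graph: nx.Graph
    tau: float
    max_distance: float
    community_assignment: dict | None = None

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def community_subgraph(self, node) -> nx.Graph:
        """Induced subgraph of the node's community (whole graph if unpartitioned)."""
        if self.community_assignment is None:
            return self.graph
        cid = self.community_assignment[node]
        members = [v for v, c in self.community_assignment.items() if c == cid]
        if len(members) == self.n_nodes:
            return self.graph
        # materialize: filtered views are too slow for path algorithms
        return self.graph.subgraph(members).copy()

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        if self.community_assignment is not None:
            nx.set_node_attributes(g, self.community_assignment, "community")
        g.graph["tau"] = self.tau
        g.graph["max_distance"] = self.max_distance
        nx.write_graphml(g, path)


@dataclass
class NetworkTriple:
    """The CN1/CN2/CN3 triple built for one query record."""

    cn1: ComplexNetwork
    cn2: ComplexNetwork
    cn3: ComplexNetwork
    query_node: object

    def __post_init__(self) -> None:
        for net in (self.cn1, self.cn2, self.cn3):
            if self.query_node not in net.graph:
                raise ValueError(f"query node {self.query_node!r} missing from a network")


@dataclass
class NodeMetrics:
    """Per-node graph statistics, raw and max-normalized over the network."""

    degree: float
    weighted_degree: float
    closeness: float
    eigenvector: float
    betweenness: float
    clustering_coefficient: float
    min_shortest_path: float  # UNREACHABLE when isolated
    two_hop_count: float
    normalized: dict[str, float] = field(default_factory=dict)


# ----------------------------------------------------------------------


def pairwise_distance(a, b) -> float:
    """Euclidean distance between two numeric records."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def build_network(
    records: np.ndarray,
    tau_factor: float = DEFAULT_TAU_FACTOR,
    node_ids=None,
    tau: float | None = None,
) -> ComplexNetwork:
    """Threshold graph over records: edge iff distance < tau_factor x mean distance.

    Edge weight = distance / max pairwise distance.  A zero-distance pair
    (duplicate records) still forms an edge, with weight 0.  Passing ``tau``
    fixes the absolute cutoff instead of deriving it from this record set —
    used so the CN1/CN2/CN3 triple shares one threshold.
    """
    X = np.asarray(records, dtype=float)
    n = len(X)
    if n < 2:
        g = nx.Graph()
        ids = list(node_ids) if node_ids is not None else list(range(n))
        g.add_nodes_from(ids)
        return ComplexNetwork(graph=g, tau=0.0, max_distance=0.0)
    if node_ids is None:
        node_ids = list(range(n))
    else:
        node_ids = list(node_ids)
        if len(node_ids) != n:
            raise ValueError("node_ids length must match record count")

    condensed = pdist(X, metric="euclidean")
    max_d = float(condensed.max())
    if max_d == 0.0:
        raise ValueError("all records identical: degenerate geometry (max distance 0)")
    if tau is None:
        tau = float(tau_factor) * float(condensed.mean())

    g = nx.Graph()
    g.add_nodes_from(node_ids)
    dmat = squareform(condensed)
    ii, jj = np.triu_indices(n, k=1)
    close = dmat[ii, jj] < tau
    for i, j in zip(ii[close], jj[close]):
        g.add_edge(node_ids[i], node_ids[j], weight=float(dmat[i, j]) / max_d)
    return ComplexNetwork(graph=g, tau=tau, max_distance=max_d)


def build_triple(
    query: np.ndarray,
    training: FeatureTable,
    tau_factor: float = DEFAULT_TAU_FACTOR,
    query_index: int | None = None,
    size_limit: int = DEFAULT_COMMUNITY_SIZE_LIMIT,
    seed: int = 0,
) -> NetworkTriple:
    """Build CN1/CN2/CN3 for one query record.

    ``query_index`` identifies the query as a row of ``training`` (its labelled
    copy is then removed from all node sets so its own label never leaks);
    ``None`` means an unseen record.  All three networks share the same
    ``tau_factor``.
    """
    y = training.outcome.to_numpy()
    X = training.matrix()
    keep = np.arange(len(X))
    if query_index is not None:
        keep = keep[keep != query_index]
    y_kept = y[keep]
    if (y_kept == 1).sum() == 0 or (y_kept == 0).sum() == 0:
        raise ValueError("training data must contain both classes")

    qvec = np.asarray(query, dtype=float).reshape(1, -1)
    query_node = "query"

    def _net(mask: np.ndarray, tau: float | None) -> ComplexNetwork:
        rows = keep[mask]
        recs = np.vstack([qvec, X[rows]])
        ids = [query_node] + [int(r) for r in rows]
        net = build_network(recs, tau_factor, node_ids=ids, tau=tau)
        return partition_communities(net, size_limit=size_limit, seed=seed)

    # one absolute threshold, derived from the full-cohort network CN1,
    # shared by CN2/CN3 so the class networks are sparser subsets of CN1
    cn1 = _net(np.ones(len(keep), dtype=bool), None)
    cn2 = _net(y_kept == 1, cn1.tau)
    cn3 = _net(y_kept == 0, cn1.tau)
    return NetworkTriple(cn1=cn1, cn2=cn2, cn3=cn3, query_node=query_node)


def partition_communities(
    network: ComplexNetwork,
    size_limit: int = DEFAULT_COMMUNITY_SIZE_LIMIT,
    seed: int = 0,
) -> ComplexNetwork:
    """Assign every node a community id; Louvain modularity when |V| > size_limit.

    Small networks form a single community, so their metrics equal
    whole-network metrics.
    """
    if network.n_nodes <= size_limit:
        network.community_assignment = {v: 0 for v in network.graph}
        return network
    # edge weights are dissimilarities, so modularity runs on the binary
    # adjacency (weight=None) rather than treating distance as affinity
    communities = nx.community.louvain_communities(network.graph, weight=None, seed=seed)
    assignment = {}
    for cid, members in enumerate(communities):
        for v in members:
            assignment[v] = cid
    network.community_assignment = assignment
    return network


# ----------------------------------------------------------------------
# node statistics


def _eigenvector_entries(
    A: np.ndarray, labels: np.ndarray, n_comp: int, tol: float = 1e-10
) -> np.ndarray:
    """Principal-eigenvector entry per node of the binary adjacency.

    Power iteration on each connected component, L2-normalized with
    non-negative entries.  The iteration runs on A + I — same principal
    eigenvector, but convergent on bipartite components whose +-lambda
    symmetry would otherwise make plain iteration oscillate.  Isolated nodes
    score 0.
    """
    out = np.zeros(len(A))
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            continue
        sub = A[np.ix_(idx, idx)] + np.eye(len(idx))
        x = np.full(len(idx), 1.0 / math.sqrt(len(idx)))
        for _ in range(100_000):
            x_new = sub @ x
            x_new /= np.linalg.norm(x_new)
            if np.linalg.norm(x_new - x) < tol:
                x = x_new
                break
            x = x_new
        out[idx] = np.abs(x)
    return out


def betweenness(network: ComplexNetwork, node) -> float:
    """Shortest-path betweenness of one node (weighted paths, unnormalized)."""
    graph = network.community_subgraph(node)
    if node not in graph:
        raise KeyError(f"node {node!r} not in network")
    return _all_betweenness(graph)[node]


def _all_betweenness(graph: nx.Graph) -> dict:
    """Unnormalized weighted shortest-path betweenness for every node.

    Delegates to igraph's C implementation (identical Brandes semantics);
    zero-weight edges (duplicate records) are not accepted there, so such
    graphs fall back to networkx.
    """
    nodes = list(graph.nodes)
    edges = list(graph.edges(data="weight", default=1.0))
    if any(w == 0.0 for _, _, w in edges):
        return nx.betweenness_centrality(graph, normalized=False, weight="weight")
    import igraph as ig

    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes),
        edges=[(index[u], index[v]) for u, v, _ in edges],
        directed=False,
    )
    vals = g.betweenness(weights=[w for _, _, w in edges] or None)
    return {v: float(vals[index[v]]) for v in nodes}


def clustering_coefficient(network: ComplexNetwork, node) -> float:
    """Triangles through the node / pairs of its neighbours; degree < 2 -> 0."""
    graph = network.community_subgraph(node)
    if node not in graph:
        raise KeyError(f"node {node!r} not in network")
    return float(nx.clustering(graph, node))


def _weighted_path_lengths(graph: nx.Graph, nodes: list) -> np.ndarray:
    """All-pairs weighted shortest-path matrix (inf where unreachable).

    Vectorized through scipy's csgraph Dijkstra; zero-weight edges (duplicate
    records) cannot be represented in a sparse matrix, so graphs containing
    them fall back to networkx Dijkstra.
    """
    n = len(nodes)
    has_zero = any(d.get("weight", 1.0) == 0.0 for _, _, d in graph.edges(data=True))
    if not has_zero:
        W = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csr")
        return csgraph.dijkstra(W, directed=False)
    index = {v: i for i, v in enumerate(nodes)}
    D = np.full((n, n), math.inf)
    for v in nodes:
        lengths = nx.single_source_dijkstra_path_length(graph, v, weight="weight")
        for u, d in lengths.items():
            D[index[v], index[u]] = d
    return D


def compute_all_metrics(graph: nx.Graph) -> dict[object, NodeMetrics]:
    """Raw and max-normalized node statistics for every node of ``graph``."""
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    W = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")

    degree = A.sum(axis=1)
    wdegree = W.sum(axis=1)

    # clustering: triangles through each node / pairs of neighbours
    triangles = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    triples = degree * (degree - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        clust = np.where(triples > 0, triangles / triples, 0.0)

    n_comp, labels = csgraph.connected_components(A, directed=False)
    eig = _eigenvector_entries(A, labels, n_comp)

    betw_dict = _all_betweenness(graph)
    betw = np.array([betw_dict[v] for v in nodes], dtype=float)

    D = _weighted_path_lengths(graph, nodes)
    np.fill_diagonal(D, math.inf)
    reachable = np.isfinite(D)
    any_reachable = reachable.any(axis=1)
    totals = np.where(any_reachable, np.where(reachable, D, 0.0).sum(axis=1), 0.0)
    with np.errstate(divide="ignore"):
        closeness = np.where(any_reachable & (totals > 0), 1.0 / np.maximum(totals, 1e-300), 0.0)
    # duplicate clusters with all-zero path sums: assign the max finite closeness
    zero_total = any_reachable & (totals == 0)
    if zero_total.any():
        finite = closeness[~zero_total]
        closeness[zero_total] = (finite.max() if finite.size else 0.0) or 1.0
    min_sp = np.where(any_reachable, np.min(np.where(reachable, D, math.inf), axis=1), math.inf)

    A2 = A + A @ A
    A2[np.arange(n), np.arange(n)] = 0.0
    two_hop = (A2 > 0).sum(axis=1).astype(float)

    def _norm(values: np.ndarray) -> np.ndarray:
        finite = values[np.isfinite(values)]
        m = finite.max() if finite.size else 0.0
        if m == 0.0:
            return np.zeros_like(values)
        return np.where(np.isfinite(values), values / m, 1.0)

    norm = {
        "degree": _norm(degree),
        "weighted_degree": _norm(wdegree),
        "closeness": _norm(closeness),
        "eigenvector": _norm(eig),
        "betweenness": _norm(betw),
        "clustering_coefficient": _norm(clust),
    }

    out: dict[object, NodeMetrics] = {}
    for i, v in enumerate(nodes):
        out[v] = NodeMetrics(
            degree=float(degree[i]),
            weighted_degree=float(wdegree[i]),
            closeness=float(closeness[i]),
            eigenvector=float(eig[i]),
            betweenness=float(betw[i]),
            clustering_coefficient=float(clust[i]),
            min_shortest_path=float(min_sp[i]),
            two_hop_count=float(two_hop[i]),
            normalized={k: float(norm[k][i]) for k in norm},
        )
    return out


def compute_node_metrics(network: ComplexNetwork, node) -> NodeMetrics:
    """Statistics of one node, computed on its community's induced subgraph."""
    graph = network.community_subgraph(node)
    if node not in graph:
        raise KeyError(f"node {node!r} not in network")
    return compute_all_metrics(graph)[node]
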