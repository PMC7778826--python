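"""Independent brute-force oracles for graph statistics on tiny graphs.

Everything here enumerates paths exhaustively or uses a dense
eigendecomposition; nothing is shared with the package's implementations.
"""

from itertools import permutations

import numpy as np

TOL = 1e-9


def all_simple_paths_costs(adj_w: dict, source, target) -> list[float]:
    """Costs of every simple path from source to target (DFS enumeration)."""
    costs = []

    def dfs(node, visited, cost):
        if node == target:
            costs.append(cost)
            return
        for nbr, w in adj_w[node].items():
            if nbr not in visited:
                dfs(nbr, visited | {nbr}, cost + w)

    dfs(source, {source}, 0.0)
    return costs


def shortest_path_length(adj_w: dict, source, target) -> float:
    costs = all_simple_paths_costs(adj_w, source, target)
    return min(costs) if costs else float("inf")


def count_shortest_paths(adj_w: dict, source, target, through=None) -> int:
    """Number of minimal-cost simple paths; optionally only those via ``through``."""
    paths = []

    def dfs(node, visited, cost, path):
        if node == target:
            paths.append((cost, path))
            return
        for nbr, w in adj_w[node].items():
            if nbr not in visited:
                dfs(nbr, visited | {nbr}, cost + w, path + [nbr])

    dfs(source, {source}, 0.0, [source])
    if not paths:
        return 0
    best = min(c for c, _ in paths)
    minimal = [p for c, p in paths if c <= best + TOL]
    if through is None:
        return len(minimal)
    return sum(1 for p in minimal if through in p[1:-1])


def betweenness_oracle(adj_w: dict, node) -> float:
    nodes = sorted(adj_w, key=str)
    total = 0.0
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if s == node or t == node:
                continue
            n_all = count_shortest_paths(adj_w, s, t)
            if n_all == 0:
                continue
            n_via = count_shortest_paths(adj_w, s, t, through=node)
            total += n_via / n_all
    return total


def closeness_oracle(adj_w: dict, node) -> float:
    lengths = [
        shortest_path_length(adj_w, node, other)
        for other in adj_w
        if other != node
    ]
    finite = [l for l in lengths if np.isfinite(l)]
    if not finite:
        return 0.0
    total = sum(finite)
    return 1.0 / total if total > 0 else float("inf")


def min_shortest_path_oracle(adj_w: dict, node) -> float:
    lengths = [
        shortest_path_length(adj_w, node, other)
        for other in adj_w
        if other != node
    ]
    finite = [l for l in lengths if np.isfinite(l)]
    return min(finite) if finite else float("inf")


def clustering_oracle(adj_w: dict, node) -> float:
    nbrs = list(adj_w[node])
    k = len(nbrs)
    if k < 2:
        return 0.0
    triangles = sum(
        1
        for i in range(k)
        for j in range(i + 1, k)
        if nbrs[j] in adj_w[nbrs[i]]
    )
    return triangles / (k * (k - 1) / 2)


def two_hop_oracle(adj_w: dict, node) -> int:
    one = set(adj_w[node])
    two = set()
    for n in one:
        two |= set(adj_w[n])
    reach = (one | two) - {node}
    return len(reach)


def eigenvector_oracle(adj_w: dict) -> dict:
    """Principal-eigenvector entries per connected component via eigh."""
    nodes = sorted(adj_w, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for v, nbrs in adj_w.items():
        for u in nbrs:
            A[index[v], index[u]] = 1.0
    # connected components by DFS
    seen, comps = set(), []
    for v in nodes:
        if v in seen:
            continue
        stack, comp = [v], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj_w[x])
        comps.append(sorted(comp, key=str))
        seen |= comp
    out = {v: 0.0 for v in nodes}
    for comp in comps:
        if len(comp) < 2:
            continue
        idx = [index[v] for v in comp]
        sub = A[np.ix_(idx, idx)]
        _, vecs = np.linalg.eigh(sub)
        vec = np.abs(vecs[:, -1])
        vec /= np.linalg.norm(vec)
        for v, val in zip(comp, vec):
            out[v] = float(val)
    return out


def graph_to_adj(graph) -> dict:
    """networkx Graph -> plain adjacency {node: {nbr: weight}}."""
    return {
        v: {u: d.get("weight", 1.0) for u, d in graph[v].items()} for v in graph
    }


def random_weighted_graph(rng, max_nodes=7):
    """Small random weighted graph as a networkx Graph."""
    import networkx as nx

    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.25, 0.95))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.05, 1.0))
    return g
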