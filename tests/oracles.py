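"""Independent brute-force oracles used across the test suite.

Deliberately naive implementations: triangle enumeration for clustering,
explicit BFS distance tables for the efficiency and closeness measures,
exhaustive shortest-path enumeration for betweenness, and a dense
eigendecomposition for eigenvector centrality.  They share no code with
the package implementations they check.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source):
    """Unweighted shortest-path distances from source (reachable nodes only)."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _adj(graph):
    return {n: set(graph[n]) for n in graph}


def oracle_clustering(graph):
    adj = _adj(graph)
    out = {}
    for node in adj:
        nbrs = sorted(adj[node])
        k = len(nbrs)
        if k < 2:
            out[node] = 0.0
            continue
        triangles = sum(
            1 for u, v in itertools.combinations(nbrs, 2) if v in adj[u]
        )
        out[node] = 2.0 * triangles / (k * (k - 1))
    return out


def oracle_local_efficiency(graph):
    adj = _adj(graph)
    out = {}
    for node in adj:
        nbrs = sorted(adj[node])
        if len(nbrs) < 2:
            out[node] = 0.0
            continue
        sub = {u: adj[u] & set(nbrs) for u in nbrs}
        total = 0.0
        pairs = 0
        for u, v in itertools.combinations(nbrs, 2):
            pairs += 1
            dist = bfs_distances(sub, u)
            if v in dist:
                total += 1.0 / dist[v]
        out[node] = total / pairs
    return out


def oracle_nodal_efficiency(graph):
    adj = _adj(graph)
    n = len(adj)
    out = {}
    for node in adj:
        dist = bfs_distances(adj, node)
        out[node] = sum(1.0 / d for t, d in dist.items() if t != node) / (n - 1)
    return out


def oracle_closeness(graph):
    adj = _adj(graph)
    n = len(adj)
    out = {}
    for node in adj:
        dist = bfs_distances(adj, node)
        r = len(dist)  # reachable set including the node itself
        total = sum(dist.values())
        if total == 0:
            out[node] = 0.0
        else:
            out[node] = ((r - 1) / (n - 1)) * ((r - 1) / total)
    return out


def _all_shortest_paths(adj, source, target):
    """Every shortest path from source to target, by breadth-limited DFS."""
    dist = bfs_distances(adj, source)
    if target not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == target:
            paths.append(list(path))
            return
        for v in adj[u]:
            if v in dist and dist[v] == dist[u] + 1 and dist.get(target, -1) >= dist[v]:
                path.append(v)
                extend(path)
                path.pop()

    extend([source])
    return [p for p in paths if len(p) - 1 == dist[target]]


def oracle_betweenness(graph):
    adj = _adj(graph)
    nodes = sorted(adj)
    n = len(nodes)
    out = {node: 0.0 for node in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for node in nodes:
            if node in (s, t):
                continue
            on = sum(1 for p in paths if node in p)
            out[node] += on / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    if norm > 0:
        for node in out:
            out[node] /= norm
    return out


def oracle_eigenvector_check(graph, values, tol=1e-9):
    """Dense-eigendecomposition check of an eigenvector-centrality result.

    ``values`` must be a unit, entrywise-nonnegative vector lying in the
    dominant eigenspace of the adjacency matrix.  When the top eigenvalue is
    simple this pins the vector down entrywise; when it is degenerate (e.g.
    two components of equal spectral radius) any unit nonnegative vector in
    the eigenspace is a valid answer, so the check is eigenspace membership.
    """
    nodes = sorted(graph)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v in graph.edges():
        a[index[u], index[v]] = a[index[v], index[u]] = 1.0
    vals, vecs = np.linalg.eigh(a)
    lam = vals[-1]
    dominant = vecs[:, vals > lam - tol]
    v = np.array([values[node] for node in nodes])
    assert abs(np.linalg.norm(v) - 1.0) < tol, "vector not L2-normalised"
    assert np.all(v >= -tol), "vector not entrywise nonnegative"
    proj = dominant @ (dominant.T @ v)
    assert np.linalg.norm(proj - v) < tol, "vector outside the dominant eigenspace"


def oracle_pearson(x, y):
    """Textbook sum-formula Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxy = float(np.sum(x * y))
    sxx = float(np.sum(x * x))
    syy = float(np.sum(y * y))
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return num / den


ORACLES = {
    "betweenness": oracle_betweenness,
    "closeness": oracle_closeness,
    "clustering": oracle_clustering,
    "nodal_efficiency": oracle_nodal_efficiency,
    "local_efficiency": oracle_local_efficiency,
}
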