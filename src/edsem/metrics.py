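"""Nodal topology measures on binary undirected graphs.

Six per-node measures — betweenness, closeness, eigenvector centrality,
clustering coefficient, nodal efficiency, local efficiency — plus the
density-integrated summary (mean over equally spaced density levels),
computed per subject across a :class:`~edsem.connectivity.ThresholdedGraphSet`.

Path-based measures delegate to networkx; eigenvector centrality is a
shifted power iteration so bipartite components converge and the vector is
L2-normalised.  Conventions for disconnected graphs: unreachable pairs
contribute zero efficiency, closeness is component-scaled, degree-0/1 nodes
have clustering and local efficiency zero.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ThresholdedGraphSet

MEASURES: tuple[str, ...] = (
    "betweenness",
    "closeness",
    "eigenvector",
    "clustering",
    "nodal_efficiency",
    "local_efficiency",
)

#: density column token marking the across-density mean
INTEGRATED = "integrated"

_POWER_TOL = 1e-10
_POWER_MAXITER = 10_000


def clustering_coefficient(graph: nx.Graph) -> dict:
    """C_i = 2 T_i / (k_i (k_i - 1)); zero for degree < 2."""
    return {n: float(c) for n, c in nx.clustering(graph).items()}


def local_efficiency(graph: nx.Graph) -> dict:
    """Global efficiency of each node's neighbour-induced subgraph (0 if k < 2)."""
    out = {}
    for node in graph:
        nbrs = list(graph[node])
        if len(nbrs) < 2:
            out[node] = 0.0
        else:
            out[node] = float(nx.global_efficiency(graph.subgraph(nbrs)))
    return out


def nodal_efficiency(graph: nx.Graph) -> dict:
    """Mean inverse shortest-path distance from each node to every other node."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    out = {}
    for node in graph:
        dist = nx.single_source_shortest_path_length(graph, node)
        inv = sum(1.0 / d for t, d in dist.items() if t != node)
        out[node] = inv / (n - 1)
    return out


def betweenness_centrality(graph: nx.Graph) -> dict:
    """Shortest-path betweenness, endpoints excluded, normalised by (n-1)(n-2)/2."""
    return {n: float(b) for n, b in nx.betweenness_centrality(graph, normalized=True).items()}


def closeness_centrality(graph: nx.Graph) -> dict:
    """Component-scaled closeness: ((r-1)/(n-1)) * ((r-1)/sum of distances)."""
    return {n: float(c) for n, c in nx.closeness_centrality(graph, wf_improved=True).items()}


def eigenvector_centrality(
    graph: nx.Graph,
    tol: float = _POWER_TOL,
    max_iter: int = _POWER_MAXITER,
) -> dict:
    """Entrywise-nonnegative dominant eigenvector of the adjacency matrix.

    Power iteration on A + I from a uniform start; the +I shift leaves the
    dominant eigenvector of a nonnegative symmetric A unchanged while making
    the iteration converge on bipartite components.  The result is
    L2-normalised; on disconnected graphs mass concentrates on the component
    with the largest spectral radius.
    """
    n = graph.number_of_nodes()
    if graph.number_of_edges() < 1:
        raise ValueError("eigenvector centrality requires at least one edge")
    nodes = list(graph)
    a = nx.to_numpy_array(graph, nodelist=nodes)
    v = np.full(n, 1.0 / np.sqrt(n))
    prev_delta = np.inf
    for it in range(max_iter):
        w = a @ v + v
        w /= np.linalg.norm(w)
        delta = float(np.max(np.abs(w - v)))
        # error forecast: delta shrinks geometrically with ratio rho, so the
        # remaining error is about delta * rho / (1 - rho)
        rho = min(delta / prev_delta, 0.9999) if prev_delta > 0 else 0.5
        prev_delta = delta
        v = w
        if delta < tol * max(1.0 - rho, 1e-4):
            break
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge in {max_iter} iterations "
            f"(n={n}, last max change {np.max(np.abs(w - v)):.3e})"
        )
    v = np.abs(v)
    v /= np.linalg.norm(v)
    return {node: float(val) for node, val in zip(nodes, v)}


_MEASURE_FUNCS = {
    "betweenness": betweenness_centrality,
    "closeness": closeness_centrality,
    "eigenvector": eigenvector_centrality,
    "clustering": clustering_coefficient,
    "nodal_efficiency": nodal_efficiency,
    "local_efficiency": local_efficiency,
}


def nodal_metrics(
    graph: nx.Graph,
    measures: Sequence[str] = MEASURES,
    nodes: Sequence | None = None,
) -> pd.DataFrame:
    """All requested measures for one graph; rows = nodes, columns = measures."""
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    values = {m: _MEASURE_FUNCS[m](graph) for m in measures}
    index = list(graph) if nodes is None else list(nodes)
    return pd.DataFrame({m: [values[m][n] for n in index] for m in measures}, index=index)


def density_integrate(values: Sequence[float]) -> float:
    """Across-density summary: plain mean (equal density spacing assumed)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to integrate")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite metric value in density integration")
    return float(arr.mean())


def metric_table(
    graph_sets: Iterable[ThresholdedGraphSet],
    measures: Sequence[str] = MEASURES,
    nodes: Sequence | None = None,
    integrate: bool = True,
) -> pd.DataFrame:
    """Long-format table: subject_id, node, measure, density, value.

    The density column holds the numeric density level, plus the token
    ``"integrated"`` for the across-density mean when ``integrate`` is set.
    """
    records = []
    for gs in graph_sets:
        per_density = {}
        for d in gs.densities:
            df = nodal_metrics(gs[d], measures, nodes)
            per_density[d] = df
            for node, row in df.iterrows():
                for m in measures:
                    records.append((gs.subject_id, node, m, d, row[m]))
        if integrate:
            stacked = {m: np.array([per_density[d][m].to_numpy() for d in gs.densities])
                       for m in measures}
            index = per_density[gs.densities[0]].index
            for m in measures:
                means = stacked[m].mean(axis=0)
                for node, val in zip(index, means):
                    records.append((gs.subject_id, node, m, INTEGRATED, float(val)))
    return pd.DataFrame(records, columns=["subject_id", "node", "measure", "density", "value"])


def pivot_metric(
    table: pd.DataFrame,
    node,
    measure: str,
    density=INTEGRATED,
) -> pd.Series:
    """Per-subject values of one node x measure x density cell, indexed by subject."""
    mask = (
        (table["node"] == node)
        & (table["measure"] == measure)
        & (table["density"] == density)
    )
    sub = table.loc[mask]
    return pd.Series(sub["value"].to_numpy(), index=sub["subject_id"].to_numpy(), name=measure)
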