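"""Connectivity matrices and density-thresholded binary graphs.

Turns parcellated BOLD time series into absolute Fisher-z correlation
matrices and families of binary undirected graphs with a fixed edge
density, plus the cohort-level selection rules (motion exclusion,
anatomical node selection) that decide which subjects and parcels
enter the graph analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: Seven equally spaced edge densities from 10% to 40% of all possible edges.
DEFAULT_DENSITIES: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)

#: Subjects with root-mean-square framewise displacement above this many mm
#: are excluded from analysis.
DEFAULT_FD_THRESHOLD: float = 0.25

#: Parcels must overlap an anatomical region of interest by strictly more
#: than this fraction to be kept as graph nodes.
DEFAULT_MIN_OVERLAP: float = 0.30

#: Correlations are clipped to +/-(1 - EPS) before atanh so that collinear
#: parcels (r = +/-1, which synthetic data can produce) stay finite.
CLIP_EPS: float = 1e-7


@dataclass(frozen=True)
class SubjectTimeSeries:
    """Parcellated signal for one subject: ``data[i, t]`` is parcel i at scan t."""

    subject_id: str
    data: np.ndarray
    parcel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "parcel_ids", tuple(str(p) for p in self.parcel_ids))
        if data.ndim != 2:
            raise ValueError("time-series data must be a 2-D parcels x timepoints array")
        n_parcels, n_time = data.shape
        if n_parcels < 2:
            raise ValueError("need at least 2 parcels")
        if n_time < 3:
            raise ValueError("need at least 3 timepoints")
        if len(self.parcel_ids) != n_parcels:
            raise ValueError("parcel_ids length does not match data rows")
        if not np.all(np.isfinite(data)):
            raise ValueError(f"subject {self.subject_id}: missing/non-finite values in time series")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def restrict(self, parcels: Sequence[str]) -> "SubjectTimeSeries":
        """Return a copy restricted to ``parcels`` (order as given)."""
        index = {p: i for i, p in enumerate(self.parcel_ids)}
        missing = [p for p in parcels if p not in index]
        if missing:
            raise KeyError(f"parcels not present: {missing}")
        rows = [index[p] for p in parcels]
        return SubjectTimeSeries(self.subject_id, self.data[rows], tuple(parcels))


@dataclass(frozen=True)
class MotionSummary:
    """Root-mean-square framewise displacement (mm) for one subject."""

    subject_id: str
    rms_fd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.rms_fd) or self.rms_fd < 0:
            raise ValueError(f"subject {self.subject_id}: rms_fd must be finite and >= 0")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric matrix of absolute Fisher-z correlations, zero diagonal."""

    values: np.ndarray
    parcel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "parcel_ids", tuple(str(p) for p in self.parcel_ids))
        n = len(self.parcel_ids)
        if v.shape != (n, n):
            raise ValueError("values must be square and match parcel_ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity values must be finite")
        if np.any(v < 0):
            raise ValueError("connectivity values must be nonnegative")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def restrict(self, parcels: Sequence[str]) -> "ConnectivityMatrix":
        index = {p: i for i, p in enumerate(self.parcel_ids)}
        rows = np.array([index[p] for p in parcels])
        return ConnectivityMatrix(self.values[np.ix_(rows, rows)], tuple(parcels))


@dataclass
class ThresholdedGraphSet:
    """One binary graph per target density for a single subject.

    Graphs are nested: under the deterministic tie rule the edge set at a
    lower density is a subset of the edge set at any higher density.
    """

    subject_id: str
    densities: tuple[float, ...]
    graphs: dict[float, nx.Graph] = field(repr=False)

    def __getitem__(self, density: float) -> nx.Graph:
        return self.graphs[density]


def compute_correlation_matrix(ts: SubjectTimeSeries) -> np.ndarray:
    """Pairwise Pearson correlations between parcel time series.

    Raises ``ValueError`` naming the first zero-variance parcel, since a
    constant signal has no defined correlation.
    """
    sd = ts.data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"subject {ts.subject_id}: parcel {ts.parcel_ids[bad[0]]!r} has zero variance"
        )
    r = np.corrcoef(ts.data)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_transform_abs(
    r_matrix: np.ndarray,
    parcel_ids: Sequence[str] | None = None,
    eps: float = CLIP_EPS,
) -> ConnectivityMatrix:
    """Absolute Fisher z-transform: ``|atanh(r)|`` entrywise, diagonal zeroed.

    ``r`` is clipped to ``+/-(1 - eps)`` first so exact +/-1 correlations
    give a large finite weight instead of infinity.  Note |atanh(r)| ==
    atanh(|r|), so the transform order does not matter.
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.abs(np.arctanh(np.clip(r, -1.0 + eps, 1.0 - eps)))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    if parcel_ids is None:
        parcel_ids = tuple(str(i) for i in range(r.shape[0]))
    return ConnectivityMatrix(z, tuple(parcel_ids))


def _edge_count(n: int, density: float) -> int:
    """Number of edges at ``density``: round-half-away-from-zero of d*n(n-1)/2."""
    exact = density * n * (n - 1) / 2.0
    return int(np.floor(exact + 0.5))


def _ranked_pairs(cm: ConnectivityMatrix) -> list[tuple[float, int, int]]:
    """All upper-triangle pairs sorted by (weight desc, node pair lexicographic asc)."""
    v = cm.values
    n = v.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, -v[iu, ju]))
    return [(v[iu[k], ju[k]], int(iu[k]), int(ju[k])) for k in order]


def binarize_at_density(cm: ConnectivityMatrix, density: float) -> nx.Graph:
    """Binary graph keeping exactly the k strongest pairs, k = round(d*n(n-1)/2).

    Ties at the cutoff are broken by lexicographic node-pair order, which
    makes the result deterministic and the graphs nested across densities.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = cm.n_parcels
    k = _edge_count(n, density)
    if k == 0:
        raise ValueError(f"density {density} yields zero edges for {n} nodes")
    g = nx.Graph()
    g.add_nodes_from(cm.parcel_ids)
    for _, i, j in _ranked_pairs(cm)[:k]:
        g.add_edge(cm.parcel_ids[i], cm.parcel_ids[j])
    return g


def build_graph_set(
    cm: ConnectivityMatrix,
    densities: Sequence[float] = DEFAULT_DENSITIES,
    subject_id: str = "",
) -> ThresholdedGraphSet:
    """One thresholded graph per density; densities must be strictly increasing."""
    densities = tuple(float(d) for d in densities)
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ValueError("densities must be strictly increasing")
    ranked = _ranked_pairs(cm)
    n = cm.n_parcels
    graphs: dict[float, nx.Graph] = {}
    for d in densities:
        k = _edge_count(n, d)
        if k == 0:
            raise ValueError(f"density {d} yields zero edges for {n} nodes")
        g = nx.Graph()
        g.add_nodes_from(cm.parcel_ids)
        for _, i, j in ranked[:k]:
            g.add_edge(cm.parcel_ids[i], cm.parcel_ids[j])
        graphs[d] = g
    return ThresholdedGraphSet(subject_id or "subject", densities, graphs)


def exclude_high_motion(
    subjects: Sequence[str],
    motion: Iterable[MotionSummary],
    threshold: float = DEFAULT_FD_THRESHOLD,
) -> list[str]:
    """Subjects retained iff rms FD <= threshold; every subject needs a record."""
    fd = {m.subject_id: m.rms_fd for m in motion}
    missing = [s for s in subjects if s not in fd]
    if missing:
        raise KeyError(f"no motion record for subjects: {missing}")
    kept = []
    for s in subjects:
        if fd[s] <= threshold:
            kept.append(s)
        else:
            logger.info("excluding subject %s: rms FD %.3f > %.3f", s, fd[s], threshold)
    return kept


def select_nodes(
    overlap_table: Mapping[str, float] | Sequence[tuple[str, float]],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> list[str]:
    """Parcels whose anatomical overlap fraction is strictly greater than the cutoff.

    Order of the input table is preserved.  An empty selection is legal but
    warned about, since no graph analysis can follow.
    """
    items = overlap_table.items() if isinstance(overlap_table, Mapping) else overlap_table
    selected = []
    for parcel, frac in items:
        if not 0 <= frac <= 1:
            raise ValueError(f"overlap fraction for {parcel!r} outside [0, 1]: {frac}")
        if frac > min_overlap:
            selected.append(parcel)
    if not selected:
        warnings.warn("node selection retained no parcels", stacklevel=2)
    return selected


def mean_connectivity(cm: ConnectivityMatrix) -> float:
    """Arithmetic mean of the upper-triangle connectivity weights."""
    iu = np.triu_indices(cm.n_parcels, k=1)
    return float(cm.values[iu].mean())


def connectivity_pipeline(
    ts: SubjectTimeSeries,
    selected_nodes: Sequence[str] | None = None,
    densities: Sequence[float] = DEFAULT_DENSITIES,
    threshold_scope: str = "selected",
) -> tuple[ConnectivityMatrix, ThresholdedGraphSet]:
    """Time series -> |Fisher z| matrix -> thresholded graph set for one subject.

    ``threshold_scope`` controls whether density thresholding happens on the
    matrix restricted to the selected nodes (``"selected"``, default) or on
    the full parcel matrix with the graphs restricted afterwards (``"all"``).
    """
    if threshold_scope not in ("selected", "all"):
        raise ValueError("threshold_scope must be 'selected' or 'all'")
    r = compute_correlation_matrix(ts)
    cm = fisher_transform_abs(r, ts.parcel_ids)
    if selected_nodes is not None and threshold_scope == "selected":
        cm = cm.restrict(selected_nodes)
        gs = build_graph_set(cm, densities, ts.subject_id)
    else:
        gs = build_graph_set(cm, densities, ts.subject_id)
        if selected_nodes is not None:
            graphs = {
                d: nx.Graph(g.subgraph(selected_nodes)) for d, g in gs.graphs.items()
            }
            gs = ThresholdedGraphSet(ts.subject_id, gs.densities, graphs)
    return cm, gs
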