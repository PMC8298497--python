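"""Plain-text readers and writers for the pipeline's tabular interfaces.

Time series travel as TSV (first column the parcel ID, remaining columns
timepoints), cohorts as a manifest CSV mapping subject IDs to files; motion
and anatomical-overlap tables as CSV; connectivity matrices as TSV; graph
sets as long edge-list TSVs; metric and scan tables as long TSVs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, MotionSummary, SubjectTimeSeries, ThresholdedGraphSet


def write_timeseries(ts: SubjectTimeSeries, path: str | Path) -> None:
    frame = pd.DataFrame(ts.data, index=list(ts.parcel_ids))
    frame.index.name = "parcel_id"
    frame.to_csv(path, sep="\t")


def read_timeseries(path: str | Path, subject_id: str | None = None) -> SubjectTimeSeries:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    sid = subject_id or Path(path).stem
    return SubjectTimeSeries(sid, frame.to_numpy(dtype=float), tuple(map(str, frame.index)))


def write_manifest(entries: dict[str, str | Path], path: str | Path) -> None:
    pd.DataFrame(
        {"subject_id": list(entries), "path": [str(p) for p in entries.values()]}
    ).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[SubjectTimeSeries]:
    """Manifest CSV (subject_id, path) -> list of subject time series."""
    manifest = pd.read_csv(path)
    root = Path(path).parent
    out = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        out.append(read_timeseries(p, str(row.subject_id)))
    return out


def write_motion(motion: Iterable[MotionSummary], path: str | Path) -> None:
    pd.DataFrame(
        [(m.subject_id, m.rms_fd) for m in motion], columns=["subject_id", "rms_fd"]
    ).to_csv(path, index=False)


def read_motion(path: str | Path) -> list[MotionSummary]:
    frame = pd.read_csv(path)
    return [MotionSummary(str(r.subject_id), float(r.rms_fd)) for r in frame.itertuples(index=False)]


def read_overlap(path: str | Path) -> list[tuple[str, float]]:
    """Overlap CSV (parcel_id, region_label, overlap_fraction) -> ordered pairs."""
    frame = pd.read_csv(path)
    return [
        (str(r.parcel_id), float(r.overlap_fraction)) for r in frame.itertuples(index=False)
    ]


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(cm.values, index=list(cm.parcel_ids), columns=list(cm.parcel_ids))
    frame.index.name = "parcel_id"
    frame.to_csv(path, sep="\t")


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(frame.to_numpy(dtype=float), tuple(map(str, frame.index)))


def write_graph_sets(graph_sets: Iterable[ThresholdedGraphSet], path: str | Path) -> None:
    """Long edge-list TSV: subject_id, density, node_u, node_v."""
    rows = []
    for gs in graph_sets:
        for d in gs.densities:
            for u, v in sorted(gs[d].edges()):
                rows.append((gs.subject_id, d, u, v))
    pd.DataFrame(rows, columns=["subject_id", "density", "node_u", "node_v"]).to_csv(
        path, sep="\t", index=False
    )


def read_graph_sets(path: str | Path) -> list[ThresholdedGraphSet]:
    frame = pd.read_csv(path, sep="\t", dtype={"node_u": str, "node_v": str})
    nodes = sorted(set(frame["node_u"]) | set(frame["node_v"]))
    out = []
    for sid, block in frame.groupby("subject_id", sort=False):
        densities = tuple(sorted(block["density"].unique()))
        graphs = {}
        for d in densities:
            g = nx.Graph()
            g.add_nodes_from(nodes)
            edges = block.loc[block["density"] == d, ["node_u", "node_v"]]
            g.add_edges_from(edges.itertuples(index=False))
            graphs[d] = g
        out.append(ThresholdedGraphSet(str(sid), densities, graphs))
    return out


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """YAML (or JSON, a YAML subset) pipeline configuration."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must define a mapping")
    return cfg
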