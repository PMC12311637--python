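"""Plain-text I/O: TSV tables, GraphML/edge-list networks, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diversity import DistanceMatrix
from .tables import AsvTable


def write_asv_table(table: AsvTable, prefix: str | Path) -> list[Path]:
    """Write counts, sample metadata and taxonomy as ``<prefix>*.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    counts_path = prefix.with_name(prefix.name + "_counts.tsv")
    table.data.to_csv(counts_path, sep="\t", index_label="sample_id")
    written.append(counts_path)
    if table.sample_metadata is not None:
        p = prefix.with_name(prefix.name + "_metadata.tsv")
        table.sample_metadata.to_csv(p, sep="\t", index_label="sample_id")
        written.append(p)
    if table.taxonomy is not None:
        p = prefix.with_name(prefix.name + "_taxonomy.tsv")
        table.taxonomy.to_csv(p, sep="\t", index_label="asv_id")
        written.append(p)
    return written


def read_asv_table(
    counts_path: str | Path,
    fraction: str,
    metadata_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
    is_relative: bool = False,
) -> AsvTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
    bad = [c for c in counts.columns if not np.issubdtype(counts[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric count column(s): {bad}")
    counts.index.name = None
    metadata = (
        pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
        if metadata_path
        else None
    )
    taxonomy = (
        pd.read_csv(taxonomy_path, sep="\t", index_col="asv_id")
        if taxonomy_path
        else None
    )
    if metadata is not None:
        metadata.index.name = None
    if taxonomy is not None:
        taxonomy.index.name = None
    return AsvTable(
        data=counts,
        fraction=fraction,
        sample_metadata=metadata,
        taxonomy=taxonomy,
        is_relative=is_relative,
    )


def write_distance_matrix(dist: DistanceMatrix, path: str | Path) -> Path:
    path = Path(path)
    dist.to_frame().to_csv(path, sep="\t", index_label="sample_id")
    return path


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    return DistanceMatrix(frame.to_numpy(), list(frame.index))


def write_network(G: nx.Graph, prefix: str | Path) -> list[Path]:
    """GraphML plus a weighted edge-list TSV (sign preserved)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    graphml = prefix.with_suffix(".graphml")
    nx.write_graphml(G, graphml)
    edges = prefix.with_name(prefix.name + "_edges.tsv")
    rows = [
        {"source": u, "target": v, **{k: d[k] for k in ("weight", "abs_weight") if k in d}}
        for u, v, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "abs_weight"]).to_csv(
        edges, sep="\t", index=False
    )
    return [graphml, edges]


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def _default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_default))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
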