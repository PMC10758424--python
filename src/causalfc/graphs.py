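"""Rolled causal-functional-connectivity graphs and their serialisation.

A rolled CFC is a weighted directed graph over brain regions.  Self-loops are
allowed (a region's past driving its own present is a modelled phenomenon).
The adjacency convention is fixed package-wide: entry ``(i, j)`` of an
adjacency matrix is the weight of edge ``i -> j`` (row = source,
column = target).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["RolledCFC", "write_graph", "read_graph"]

GRAPH_FORMATS = ("adjacency-csv", "edge-list-tsv", "graphml")


@dataclass(frozen=True)
class RolledCFC:
    """Weighted directed graph over regions; the subject-level CFC.

    ``weights`` maps ordered pairs ``(source, target)`` to a signed causal
    strength.  Positive weights are read as excitatory influence, negative as
    inhibitory.
    """

    region_labels: tuple[str, ...]
    weights: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.region_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate region labels")
        known = set(labels)
        w = {}
        for (u, v), value in dict(self.weights).items():
            if u not in known or v not in known:
                raise ValueError(f"edge ({u!r}, {v!r}) uses unknown region label")
            w[(u, v)] = float(value)
        object.__setattr__(self, "region_labels", labels)
        object.__setattr__(self, "weights", w)

    # -- queries ---------------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.weights)

    def weight(self, source: str, target: str, default: float = 0.0) -> float:
        return self.weights.get((source, target), default)

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self.weights

    # -- conversions -----------------------------------------------------
    def to_adjacency(self) -> pd.DataFrame:
        """Labelled square matrix, entry (i, j) = weight of i -> j."""
        n = self.n_regions
        mat = np.zeros((n, n))
        idx = {lab: i for i, lab in enumerate(self.region_labels)}
        for (u, v), w in self.weights.items():
            mat[idx[u], idx[v]] = w
        return pd.DataFrame(mat, index=self.region_labels, columns=self.region_labels)

    @classmethod
    def from_adjacency(cls, adj: pd.DataFrame) -> "RolledCFC":
        if list(adj.index) != list(adj.columns):
            raise ValueError("adjacency must have identical row/column labels")
        labels = tuple(str(x) for x in adj.index)
        weights = {
            (labels[i], labels[j]): float(adj.iat[i, j])
            for i in range(len(labels))
            for j in range(len(labels))
            if adj.iat[i, j] != 0.0
        }
        return cls(labels, weights)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.region_labels)
        for (u, v), w in self.weights.items():
            g.add_edge(u, v, weight=w)
        return g


def _sorted_edges(graph: RolledCFC) -> list[tuple[str, str, float]]:
    order = {lab: i for i, lab in enumerate(graph.region_labels)}
    return sorted(
        ((u, v, w) for (u, v), w in graph.weights.items()),
        key=lambda e: (order[e[0]], order[e[1]]),
    )


def write_graph(graph: RolledCFC, path: str | Path, format: str = "adjacency-csv") -> None:
    """Serialise a rolled CFC deterministically (label order).

    ``adjacency-csv``: labelled square matrix, absent edges written as 0.
    ``edge-list-tsv``: columns source, target, weight.
    ``graphml``: networkx GraphML with a ``weight`` edge attribute.
    """
    path = Path(path)
    if format == "adjacency-csv":
        graph.to_adjacency().to_csv(path, float_format="%.17g")
    elif format == "edge-list-tsv":
        rows = _sorted_edges(graph)
        df = pd.DataFrame(rows, columns=["source", "target", "weight"])
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
    else:
        raise ValueError(f"unknown graph format {format!r}; choose from {GRAPH_FORMATS}")


def read_graph(
    path: str | Path,
    format: str = "adjacency-csv",
    region_labels: Iterable[str] | None = None,
) -> RolledCFC:
    """Inverse of :func:`write_graph`.

    For edge lists, ``region_labels`` supplies the node universe (isolated
    regions are not recoverable from edges alone); when omitted the labels
    found in the file are used in first-appearance order.
    """
    path = Path(path)
    if format == "adjacency-csv":
        adj = pd.read_csv(path, index_col=0)
        adj.index = adj.index.astype(str)
        adj.columns = adj.columns.astype(str)
        return RolledCFC.from_adjacency(adj)
    if format == "edge-list-tsv":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        if region_labels is None:
            seen: dict[str, None] = {}
            for lab in list(df["source"]) + list(df["target"]):
                seen.setdefault(lab)
            region_labels = seen
        weights = {
            (r.source, r.target): float(r.weight) for r in df.itertuples(index=False)
        }
        return RolledCFC(tuple(region_labels), weights)
    if format == "graphml":
        g = nx.read_graphml(path)
        labels = region_labels if region_labels is not None else g.nodes
        weights = {(u, v): float(d.get("weight", 1.0)) for u, v, d in g.edges(data=True)}
        return RolledCFC(tuple(labels), weights)
    raise ValueError(f"unknown graph format {format!r}; choose from {GRAPH_FORMATS}")
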