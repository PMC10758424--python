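"""Exact oracles and enumeration utilities for validating the inference.

These are first-class testing instruments: an exact d-separation
conditional-independence oracle (substituting for a statistical CI test,
PC must then recover the true skeleton exactly), exhaustive enumeration of
small DAGs, and construction of the oracle unrolled DAG implied by a
ground-truth structural VAR (for weight read-out without structure search).
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable, Iterator, Sequence

import networkx as nx

from .synthetic import GroundTruthModel
from .tpc import UnrolledDAG, Variable

__all__ = [
    "dsep_ci_oracle",
    "enumerate_dags",
    "dag_skeleton",
    "oracle_unrolled_dag",
]


def dsep_ci_oracle(
    edges: Iterable[tuple[int, int]], n_nodes: int
) -> Callable[[int, int, tuple], tuple[bool, float]]:
    """Exact CI oracle for a known DAG over nodes ``0..n_nodes-1``.

    Returns a callable with the PC test signature ``(i, j, cond) ->
    (independent, p)`` that answers d-separation queries exactly (p is 1.0
    for separated pairs, 0.0 otherwise).
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("oracle graph must be a DAG")

    def ci(i: int, j: int, cond: tuple = ()) -> tuple[bool, float]:
        sep = nx.is_d_separator(g, {i}, {j}, set(cond))
        return sep, 1.0 if sep else 0.0

    return ci


def enumerate_dags(n_nodes: int) -> Iterator[frozenset[tuple[int, int]]]:
    """Yield the edge set of every labelled DAG on ``n_nodes`` nodes.

    Brute force over all directed edge subsets with an acyclicity filter;
    intended for n <= 4 (543 DAGs) where it is exhaustive and fast.
    """
    pairs = [
        (i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j
    ]
    for mask in range(2 ** len(pairs)):
        edges = [pairs[k] for k in range(len(pairs)) if mask >> k & 1]
        g = nx.DiGraph(edges)
        g.add_nodes_from(range(n_nodes))
        if nx.is_directed_acyclic_graph(g):
            yield frozenset(edges)


def dag_skeleton(edges: Iterable[tuple[int, int]]) -> set[frozenset]:
    """Undirected adjacency (the true PC-skeleton) of a DAG edge set."""
    return {frozenset(e) for e in edges}


def oracle_unrolled_dag(
    model: GroundTruthModel, group: str | None = None, tau: int = 1
) -> UnrolledDAG:
    """The unrolled DAG a perfect structure-search would return.

    Nodes are (region, offset) for offsets ``0..tau``; each lag-1
    coefficient ``i -> j`` contributes edges ``(i, s) -> (j, s+1)`` and each
    contemporaneous coefficient ``(i, s) -> (j, s)`` for every offset.
    Useful for reading out per-subject edge weights by regression without
    running the skeleton search.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1 to represent lagged edges")
    con, lag = model.coeffs_for(group)
    labels = model.region_labels
    directed: set[tuple[Variable, Variable]] = set()
    n = model.n_regions
    for i in range(n):
        for j in range(n):
            if lag[i, j] != 0:
                for s in range(tau):
                    directed.add(((labels[i], s), (labels[j], s + 1)))
            if con[i, j] != 0:
                for s in range(tau + 1):
                    directed.add(((labels[i], s), (labels[j], s)))
    nodes = tuple((lab, s) for s in range(tau + 1) for lab in labels)
    return UnrolledDAG(
        nodes=nodes,
        directed=frozenset(directed),
        undirected=frozenset(),
        undirected_policy="drop",
    )
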