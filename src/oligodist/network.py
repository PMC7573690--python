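"""Degree statistics of protein-protein interaction graphs.

The quantities follow the network conventions of the analysis: average node
degree <d> = 2E/N, the degree distribution P(k) (fraction of nodes with
degree k), a per-protein "connection probability" degree/2E (the share of all
edge endpoints a protein accounts for — distinct from P(k), and exposed
separately), and average degree stratified by homo-oligomer class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import EmptyInputError, InsufficientDataError
from .io import PPIGraph, ProteinRecord

__all__ = [
    "DegreeSummary",
    "ClassDegreeTable",
    "summarize_degrees",
    "degree_by_oligomer_class",
    "correlation_degree_vs_k",
]


@dataclass(frozen=True)
class DegreeSummary:
    """Node-level and network-level degree statistics of a PPI graph."""

    degree_of: dict[str, int]
    distribution: dict[int, float]  # degree k -> fraction of nodes
    connection_prob: dict[str, float]  # protein -> degree / 2E
    mean_degree: float  # <d> = 2E/N
    n_nodes: int
    n_edges: int


@dataclass(frozen=True)
class ClassDegreeTable:
    """Average degree per homo-oligomer class k.

    members: class k -> number of annotated proteins found in the graph;
    mean_degree: class k -> mean degree of those proteins;
    missing: class k -> annotated proteins absent from the graph (excluded).
    """

    members: dict[int, int]
    mean_degree: dict[int, float]
    missing: dict[int, int]
    join_rate: float  # share of annotated proteins present in the graph


def summarize_degrees(graph: PPIGraph) -> DegreeSummary:
    """Compute all degree statistics of a graph (isolated nodes included)."""
    n = graph.number_of_nodes()
    if n == 0:
        raise EmptyInputError("graph has no nodes")
    e = graph.number_of_edges()
    degree_of = {node: int(d) for node, d in graph.degree()}
    degs = np.array(list(degree_of.values()), dtype=np.int64)
    uniq, counts = np.unique(degs, return_counts=True)
    distribution = {int(k): float(c / n) for k, c in zip(uniq, counts)}
    two_e = 2 * e
    connection_prob = {
        node: (d / two_e if two_e else 0.0) for node, d in degree_of.items()
    }
    return DegreeSummary(
        degree_of=degree_of,
        distribution=distribution,
        connection_prob=connection_prob,
        mean_degree=two_e / n,
        n_nodes=n,
        n_edges=e,
    )


def degree_by_oligomer_class(
    graph: PPIGraph,
    records: Iterable[ProteinRecord],
    classes: Sequence[int] = (2, 4, 6, 8),
) -> ClassDegreeTable:
    """Average node degree of proteins in each homo-oligomer class.

    Proteins annotated with a class but absent from the graph are excluded
    from the class mean (interaction files list only interacting proteins)
    and counted in ``missing``.
    """
    by_class: dict[int, list[int]] = {k: [] for k in classes}
    missing = {k: 0 for k in classes}
    n_annotated = 0
    n_joined = 0
    for r in records:
        if not r.is_homo or r.oligomer_k not in by_class:
            continue
        n_annotated += 1
        if graph.has_node(r.protein_id):
            n_joined += 1
            by_class[r.oligomer_k].append(graph.degree(r.protein_id))
        else:
            missing[r.oligomer_k] += 1
    if n_joined == 0:
        raise EmptyInputError("no annotated proteins present in the graph")
    members = {k: len(v) for k, v in by_class.items() if v}
    mean_degree = {k: float(np.mean(by_class[k])) for k in members}
    return ClassDegreeTable(
        members=members,
        mean_degree=mean_degree,
        missing={k: m for k, m in missing.items() if m},
        join_rate=n_joined / n_annotated,
    )


def correlation_degree_vs_k(table: ClassDegreeTable) -> tuple[float, float]:
    """Pearson correlation and OLS slope of (class k, mean degree).

    Quantifies whether connectivity varies with oligomerization state; a
    near-zero correlation reproduces the homogeneous-connectivity finding.
    Returns ``(r, slope)``; a constant table yields ``(0.0, 0.0)``.
    """
    ks = sorted(table.mean_degree)
    if len(ks) < 3:
        raise InsufficientDataError(f"need >= 3 classes, got {len(ks)}")
    x = np.array(ks, dtype=float)
    y = np.array([table.mean_degree[k] for k in ks], dtype=float)
    if np.allclose(y, y[0]):
        return 0.0, 0.0
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(stats.linregress(x, y).slope)
    return r, slope
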