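"""Target-network construction from MI matrices.

A target network is an undirected graph over selected genes whose edges are
the gene pairs with mutual information above a data-driven threshold.  The
threshold is the null maximum of a permutation test: each gene's sample
values are permuted independently (destroying all between-gene dependence
while preserving marginals), the full pairwise MI matrix is recomputed, and
the largest off-diagonal value is recorded; over ``n_perm`` repetitions the
largest recorded maximum becomes the threshold.  Edges must exceed it
strictly — the threshold itself is a null value.

Clustergram support: hierarchical clustering of the MI-matrix rows under
Euclidean distance (average linkage) yields a leaf order for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

from .mutual_info import MIMatrix, pairwise_mi

__all__ = [
    "TargetNetwork",
    "ClusterOrder",
    "permutation_null_maxima",
    "permutation_threshold",
    "build_network",
    "cluster_order",
    "write_network",
    "read_network",
]


@dataclass
class TargetNetwork:
    """Undirected MI-weighted gene graph with its provenance threshold."""

    graph: nx.Graph
    threshold: float
    permutation_count: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ClusterOrder:
    """Leaf order and merge tree from hierarchical clustering of MI rows."""

    leaf_order: list[str]
    linkage_matrix: np.ndarray


def permutation_null_maxima(
    values: np.ndarray,
    h: float,
    n_perm: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Max off-diagonal MI of each independently-permuted replicate.

    Each repetition permutes every gene's samples independently, recomputes
    the pairwise MI matrix, and records its largest off-diagonal entry.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation repetition")
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(rng)
    N, M = values.shape
    maxima = np.empty(n_perm)
    for rep in range(n_perm):
        perm = np.empty_like(values)
        for g in range(N):
            perm[g] = values[g, rng.permutation(M)]
        mi = pairwise_mi(perm, h).values
        off = mi[~np.eye(N, dtype=bool)]
        maxima[rep] = off.max()
    return maxima


def permutation_threshold(
    values: np.ndarray,
    h: float,
    n_perm: int = 30,
    rng: np.random.Generator | int | None = None,
) -> float:
    """MI threshold: the largest null maximum over ``n_perm`` repetitions."""
    return float(permutation_null_maxima(values, h, n_perm, rng).max())


def build_network(
    m: MIMatrix, threshold: float, permutation_count: int = 0
) -> TargetNetwork:
    """Keep edges with MI strictly above the threshold; keep isolated nodes."""
    g = nx.Graph()
    g.add_nodes_from(m.gene_ids)
    iu = np.triu_indices(m.n_genes, k=1)
    for i, j in zip(*iu):
        w = m.values[i, j]
        if w > threshold:
            g.add_edge(m.gene_ids[i], m.gene_ids[j], mi=float(w))
    return TargetNetwork(graph=g, threshold=float(threshold),
                         permutation_count=permutation_count)


def cluster_order(m: MIMatrix) -> ClusterOrder:
    """Order genes by average-linkage clustering of MI rows (Euclidean).

    Ties are resolved by scipy's deterministic merge rules, which follow
    input order; identical rows merge first at height 0.
    """
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes to cluster")
    Z = linkage(m.values, method="average", metric="euclidean")
    leaves = leaves_list(Z)
    return ClusterOrder(
        leaf_order=[m.gene_ids[i] for i in leaves], linkage_matrix=Z
    )


def write_network(net: TargetNetwork, path, format: str = "edge-list") -> None:
    """Serialize a target network as GraphML or 3-column edge-list TSV."""
    if format == "graphml":
        g = net.graph.copy()
        g.graph["threshold"] = net.threshold
        g.graph["permutation_count"] = net.permutation_count
        nx.write_graphml(g, path)
    elif format == "edge-list":
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tmi\n")
            for a, b, d in net.graph.edges(data=True):
                fh.write(f"{a}\t{b}\t{d['mi']:.12g}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path) -> TargetNetwork:
    """Read a GraphML file written by :func:`write_network`."""
    g = nx.read_graphml(path)
    threshold = float(g.graph.get("threshold", float("-inf")))
    n_perm = int(g.graph.get("permutation_count", 0))
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for a, b, d in g.edges(data=True):
        h.add_edge(a, b, mi=float(d["mi"]))
    return TargetNetwork(graph=h, threshold=threshold, permutation_count=n_perm)
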