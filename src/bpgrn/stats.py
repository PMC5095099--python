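"""Topology statistics of regulatory networks.

Five structural parameters summarise a network: average path length (L),
average clustering coefficient (C), average degree (K), modularity (Q) and
graph density (D).  All five are computed on the undirected projection of the
directed network — the only convention consistent with the identities the
parameters satisfy jointly (D = K / (N - 1); L = 1 for a network whose
components are single edges).

Notes on the individual definitions:

* L averages shortest-path distances over *connected* unordered node pairs
  (pairs in different components are excluded, not counted as infinite).
* C_i is the fraction of realised edges among the neighbours of node i; nodes
  with fewer than two neighbours contribute C_i = 0, and C is the mean over
  all nodes.
* K is the mean number of distinct neighbours per node (2 * edges / nodes).
* Q is the Newman-Girvan modularity of a community partition: with h_ii the
  fraction of edges inside community i, h_ij (i != j) half the fraction
  running between i and j, and a_i the i-th row sum of H,
  Q = sum_i (h_ii - a_i**2).  Communities come from seeded Louvain
  maximisation unless a partition is supplied.
* D = K / (N - 1), the realised fraction of possible undirected edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedStatisticError
from .network import RegulatoryNetwork

__all__ = [
    "NetworkStats",
    "CommunityPartition",
    "average_path_length",
    "average_clustering_coefficient",
    "average_degree",
    "detect_communities",
    "modularity",
    "graph_density",
    "compute_stats",
    "compare_stats",
]

PARAMETERS = ("L", "C", "K", "Q", "D")


@dataclass
class CommunityPartition:
    """A hard partition of genes into communities indexed 1..k."""

    assignment: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidInputError("k must be >= 1")
        labels = set(self.assignment.values())
        if labels != set(range(1, self.k + 1)):
            raise InvalidInputError(
                "community indices must be contiguous 1..k"
            )


@dataclass
class NetworkStats:
    """The five structural parameters of one network.

    A parameter that is undefined for the given graph (e.g. L on an edgeless
    network) is ``None``, with the reason recorded in ``undefined``.
    """

    L: Optional[float]
    C: float
    K: float
    Q: Optional[float]
    D: Optional[float]
    n_nodes: int
    n_edges: int
    threshold: Optional[float] = None
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "L": self.L, "C": self.C, "K": self.K, "Q": self.Q, "D": self.D,
            "n_nodes": self.n_nodes, "n_edges": self.n_edges,
            "threshold": self.threshold, "undefined": dict(self.undefined),
        }


def average_path_length(net: RegulatoryNetwork) -> float:
    """Mean shortest-path distance over connected unordered node pairs."""
    g = net.to_undirected()
    if g.number_of_edges() == 0:
        raise UndefinedStatisticError("average path length of an edgeless "
                                      "network is undefined")
    total = 0
    pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())  # counts ordered pairs, d(i,i)=0
        pairs += len(comp) * (len(comp) - 1) // 2
    return total / (2 * pairs)


def average_clustering_coefficient(net: RegulatoryNetwork) -> float:
    """Mean over all nodes of the realised fraction of neighbour-neighbour
    edges (0 for nodes with fewer than two neighbours)."""
    g = net.to_undirected()
    return float(nx.average_clustering(g)) if g.number_of_nodes() else 0.0


def average_degree(net: RegulatoryNetwork) -> float:
    """Mean number of distinct adjacent nodes."""
    g = net.to_undirected()
    n = g.number_of_nodes()
    return 2.0 * g.number_of_edges() / n if n else 0.0


def graph_density(net: RegulatoryNetwork) -> float:
    """D = K / (N - 1): realised fraction of possible undirected edges."""
    g = net.to_undirected()
    n = g.number_of_nodes()
    if n < 2:
        raise UndefinedStatisticError("density needs at least 2 nodes")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def detect_communities(net: RegulatoryNetwork, seed: int = 0
                       ) -> CommunityPartition:
    """Louvain community detection on the undirected projection.

    Deterministic for a given seed.  Communities are numbered 1..k in order
    of their first member under the network's gene ordering; isolated nodes
    form their own singleton communities.
    """
    g = net.to_undirected()
    if g.number_of_edges() == 0:
        raise UndefinedStatisticError("community structure of an edgeless "
                                      "network is undefined")
    comms = nx.community.louvain_communities(g, seed=seed)
    order = {gene: i for i, gene in enumerate(net.gene_ids)}
    comms = sorted(comms, key=lambda c: min(order[m] for m in c))
    assignment = {}
    for idx, members in enumerate(comms, start=1):
        for m in members:
            assignment[m] = idx
    return CommunityPartition(assignment=assignment, k=len(comms))


def modularity(net: RegulatoryNetwork, partition: CommunityPartition) -> float:
    """Newman-Girvan modularity of *partition* on the undirected projection.

    Builds the k x k community mixing matrix H — h_ii the fraction of edges
    inside community i, h_ij = h_ji half the fraction between i and j, so the
    row sums a_i total 1 — and returns ``sum_i (h_ii - a_i**2)``.
    """
    g = net.to_undirected()
    missing = [v for v in g.nodes if v not in partition.assignment]
    if missing:
        raise InvalidInputError(f"partition does not cover nodes {missing[:5]}")
    m = g.number_of_edges()
    if m == 0:
        raise UndefinedStatisticError("modularity of an edgeless network is "
                                      "undefined")
    k = partition.k
    H = np.zeros((k, k))
    for u, v in g.edges:
        cu = partition.assignment[u] - 1
        cv = partition.assignment[v] - 1
        if cu == cv:
            H[cu, cu] += 1.0 / m
        else:
            H[cu, cv] += 0.5 / m
            H[cv, cu] += 0.5 / m
    a = H.sum(axis=1)
    return float(np.sum(np.diag(H) - a**2))


def compute_stats(net: RegulatoryNetwork, seed: int = 0,
                  partition: Optional[CommunityPartition] = None
                  ) -> NetworkStats:
    """Bundle all five parameters for one network.

    Undefined components are reported as ``None`` with a reason instead of
    aborting the bundle.
    """
    undefined: dict[str, str] = {}
    try:
        L = average_path_length(net)
    except UndefinedStatisticError as exc:
        L, undefined["L"] = None, str(exc)
    C = average_clustering_coefficient(net)
    K = average_degree(net)
    try:
        if partition is None:
            partition = detect_communities(net, seed=seed)
        Q = modularity(net, partition)
    except UndefinedStatisticError as exc:
        Q, undefined["Q"] = None, str(exc)
    try:
        D = graph_density(net)
    except UndefinedStatisticError as exc:
        D, undefined["D"] = None, str(exc)
    g = net.to_undirected()
    return NetworkStats(
        L=L, C=C, K=K, Q=Q, D=D,
        n_nodes=g.number_of_nodes(), n_edges=g.number_of_edges(),
        threshold=net.threshold_used, undefined=undefined,
    )


def compare_stats(stats_by_condition: Mapping[str, Sequence[tuple[float, NetworkStats]]],
                  reference: str) -> pd.DataFrame:
    """Per-threshold, per-parameter differences against a reference condition.

    Parameters
    ----------
    stats_by_condition : mapping condition -> list of (threshold, NetworkStats)
        All conditions must share the same threshold grid, in the same order.
    reference : str
        The condition every other condition is subtracted against
        (difference = condition - reference).

    Returns
    -------
    DataFrame with columns ``threshold``, ``parameter``, ``condition``,
    ``difference`` (NaN where either side is undefined).
    """
    if reference not in stats_by_condition:
        raise InvalidInputError(f"reference condition {reference!r} missing")
    grids = {
        cond: [round(t, 12) for t, _ in entries]
        for cond, entries in stats_by_condition.items()
    }
    ref_grid = grids[reference]
    for cond, grid in grids.items():
        if grid != ref_grid:
            raise InvalidInputError(
                f"threshold grid of {cond!r} does not match {reference!r}"
            )
    ref_stats = [s for _, s in stats_by_condition[reference]]
    rows = []
    for cond, entries in stats_by_condition.items():
        if cond == reference:
            continue
        for (thr, st), ref in zip(entries, ref_stats):
            for param in PARAMETERS:
                a = getattr(st, param)
                b = getattr(ref, param)
                diff = (a - b) if (a is not None and b is not None) else np.nan
                rows.append({"threshold": thr, "parameter": param,
                             "condition": cond, "difference": diff})
    return pd.DataFrame(rows, columns=["threshold", "parameter", "condition",
                                       "difference"])
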