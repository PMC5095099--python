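"""From trained weights to a signed directed regulatory network.

An edge i -> j is retained when its weight ratio

    lambda_ij = |W[i, j]| / sum_k |W[k, j]|

(the share of target j's total absolute incoming weight carried by source i)
is at least the chosen threshold.  Surviving edges keep the raw weight, the
ratio, and a sign: activation for positive weights, inhibition for negative.
The canonical threshold sweep is the ten-point grid 0.50, 0.55, ..., 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np

from .bp import WeightMatrix
from .errors import InvalidInputError

__all__ = [
    "DEFAULT_THRESHOLDS",
    "Edge",
    "WeightRatioMatrix",
    "RegulatoryNetwork",
    "weight_ratio_matrix",
    "build_network",
    "sweep_thresholds",
]

#: The canonical ten-point threshold sweep grid.
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95,
)

Sign = Literal["activation", "inhibition"]


class Edge(NamedTuple):
    """A directed regulatory edge source -> target."""

    source: str
    target: str
    weight: float
    ratio: float
    sign: Sign


@dataclass
class WeightRatioMatrix:
    """Per-edge weight ratios; column j sums to 1 over nonzero entries
    (or is all zero when target j has no incoming weight)."""

    gene_ids: list[str]
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=np.float64)
        n = len(self.gene_ids)
        if self.ratios.shape != (n, n):
            raise InvalidInputError(f"ratios must be {n}x{n}")


@dataclass
class RegulatoryNetwork:
    """A signed, weighted, directed gene regulatory network.

    Nodes are all genes (isolated genes included); ``edges`` hold the directed
    regulations that survived thresholding.  ``method`` distinguishes networks
    built from BP weights (``"bp"``) from Pearson relevance networks
    (``"pearson"``, encoded as symmetric directed edge pairs).
    """

    gene_ids: list[str]
    edges: list[Edge]
    threshold_used: float
    method: str = "bp"

    def __post_init__(self) -> None:
        known = set(self.gene_ids)
        for e in self.edges:
            if e.source == e.target:
                raise InvalidInputError(f"self-loop on {e.source!r}")
            if e.source not in known or e.target not in known:
                raise InvalidInputError(f"edge {e.source}->{e.target} uses "
                                        "unknown gene ids")

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        """Number of directed edges (a relevance network counts each
        undirected link twice, once per direction)."""
        return len(self.edges)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def in_degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.gene_ids}
        for e in self.edges:
            deg[e.target] += 1
        return deg

    def out_degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.gene_ids}
        for e in self.edges:
            deg[e.source] += 1
        return deg

    def to_undirected(self) -> nx.Graph:
        """Undirected projection with all genes as nodes (used by every
        topology statistic)."""
        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        for e in self.edges:
            g.add_edge(e.source, e.target)
        return g

    def to_directed(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        for e in self.edges:
            g.add_edge(e.source, e.target, weight=e.weight, ratio=e.ratio,
                       sign=e.sign)
        return g


def weight_ratio_matrix(W: WeightMatrix) -> WeightRatioMatrix:
    """Normalise each target's incoming absolute weights to ratios.

    ``ratio[i, j] = |W[i, j]| / sum_k |W[k, j]|``; a column whose absolute
    sum is zero maps to an all-zero column.
    """
    absW = np.abs(W.W)
    colsum = absW.sum(axis=0)
    safe = np.where(colsum == 0.0, 1.0, colsum)
    ratios = absW / safe
    ratios[:, colsum == 0.0] = 0.0
    return WeightRatioMatrix(gene_ids=list(W.gene_ids), ratios=ratios)


def build_network(W: WeightMatrix, ratios: Optional[WeightRatioMatrix] = None,
                  threshold: float = 0.85) -> RegulatoryNetwork:
    """Threshold the weight-ratio matrix into a regulatory network.

    Edge i -> j exists iff ``ratio[i, j] >= threshold`` and ``W[i, j] != 0``
    (edges exactly at the threshold are kept; zero weights never form edges,
    even at threshold 0).
    """
    if not 0.0 <= threshold <= 1.0:
        raise InvalidInputError(f"threshold must be in [0, 1], got {threshold}")
    if ratios is None:
        ratios = weight_ratio_matrix(W)
    if ratios.gene_ids != W.gene_ids or ratios.ratios.shape != W.W.shape:
        raise InvalidInputError("weight and ratio matrices are not conformable")
    genes = W.gene_ids
    n = len(genes)
    edges: list[Edge] = []
    keep = (ratios.ratios >= threshold) & (W.W != 0.0)
    src_idx, tgt_idx = np.nonzero(keep)
    for i, j in zip(src_idx.tolist(), tgt_idx.tolist()):
        w = float(W.W[i, j])
        edges.append(Edge(
            source=genes[i], target=genes[j], weight=w,
            ratio=float(ratios.ratios[i, j]),
            sign="activation" if w > 0 else "inhibition",
        ))
    return RegulatoryNetwork(gene_ids=list(genes), edges=edges,
                             threshold_used=float(threshold), method="bp")


def sweep_thresholds(W: WeightMatrix,
                     thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                     ) -> list[RegulatoryNetwork]:
    """Build one network per threshold (default: the canonical ten-point
    grid).  Edge sets are nested: higher thresholds keep subsets."""
    thresholds = list(thresholds)
    if not thresholds:
        raise InvalidInputError("thresholds must be non-empty")
    ratios = weight_ratio_matrix(W)
    return [build_network(W, ratios, thr) for thr in thresholds]
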