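"""Pearson relevance-network baseline.

A co-expression network with an (undirected) edge wherever the absolute
pairwise Pearson correlation reaches a threshold (default 0.85).  Edges carry
the correlation sign (activation for r > 0, inhibition for r < 0).  Zero-
variance genes have undefined correlations and never form edges.  The network
is encoded as symmetric directed edge pairs so that all topology statistics
and the degree-based differential-gene machinery run on it unchanged; the
zero-degree census quantifies how many genes the baseline leaves isolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import InvalidInputError
from .matrix import ExpressionMatrix
from .network import Edge, RegulatoryNetwork

__all__ = [
    "CorrelationMatrix",
    "pearson_correlation_matrix",
    "relevance_network",
    "zero_degree_count",
    "RelevanceNetworkInferrer",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlations with undefined pairs recorded.

    ``r`` holds NaN for pairs involving a zero-variance gene;
    ``undefined_pairs`` lists those pairs (i < j in gene order).
    """

    gene_ids: list[str]
    r: np.ndarray
    undefined_pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        n = len(self.gene_ids)
        if self.r.shape != (n, n):
            raise InvalidInputError(f"r must be {n}x{n}")


def pearson_correlation_matrix(matrix: ExpressionMatrix) -> CorrelationMatrix:
    """All pairwise Pearson correlations over samples.

    Genes with zero variance across samples yield undefined (NaN)
    correlations with every other gene (and themselves); defined diagonal
    entries are exactly 1.
    """
    if matrix.n_samples < 2:
        raise InvalidInputError("need at least 2 samples for correlation")
    X = matrix.values
    centered = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centered, centered)
    sd = np.sqrt(ss)
    # numerically constant genes: tolerance scaled to the gene's magnitude,
    # so that rounding residue from centering never passes as variation
    scale = np.maximum(1.0, np.max(np.abs(X), axis=1))
    defined = sd > 1e-12 * matrix.n_samples * scale
    cov = centered @ centered.T
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    r = np.clip(r, -1.0, 1.0)
    r[~defined, :] = np.nan
    r[:, ~defined] = np.nan
    np.fill_diagonal(r, np.where(defined, 1.0, np.nan))
    order = {g: i for i, g in enumerate(matrix.gene_ids)}
    undefined_pairs = set()
    bad = [g for g, ok in zip(matrix.gene_ids, defined) if not ok]
    for g in bad:
        for h in matrix.gene_ids:
            if h == g:
                continue
            pair = (g, h) if order[g] < order[h] else (h, g)
            undefined_pairs.add(pair)
    return CorrelationMatrix(gene_ids=list(matrix.gene_ids), r=r,
                             undefined_pairs=undefined_pairs)


def relevance_network(corr: CorrelationMatrix, r_threshold: float = 0.85
                      ) -> RegulatoryNetwork:
    """Threshold |r| into an undirected relevance network.

    Each retained gene pair contributes two directed edges (one per
    direction) with weight r, ratio |r| and the sign of r.  Undefined
    correlations never form edges.
    """
    if not 0.0 <= r_threshold <= 1.0:
        raise InvalidInputError(f"r_threshold must be in [0, 1], got "
                                f"{r_threshold}")
    genes = corr.gene_ids
    n = len(genes)
    edges: list[Edge] = []
    for i in range(n):
        for j in range(i + 1, n):
            rij = corr.r[i, j]
            if np.isnan(rij) or abs(rij) < r_threshold:
                continue
            sign = "activation" if rij > 0 else "inhibition"
            edges.append(Edge(genes[i], genes[j], float(rij), abs(float(rij)),
                              sign))
            edges.append(Edge(genes[j], genes[i], float(rij), abs(float(rij)),
                              sign))
    return RegulatoryNetwork(gene_ids=list(genes), edges=edges,
                             threshold_used=float(r_threshold),
                             method="pearson")


def zero_degree_count(net: RegulatoryNetwork) -> int:
    """Number of genes with no incident edge in either direction."""
    touched = set()
    for e in net.edges:
        touched.add(e.source)
        touched.add(e.target)
    return len(net.gene_ids) - len(touched)


class RelevanceNetworkInferrer(BaseEstimator):
    """Scikit-learn-style wrapper for the Pearson relevance baseline.

    ``fit`` computes the correlation matrix from samples x genes data;
    :meth:`network` thresholds it.
    """

    def __init__(self, r_threshold: float = 0.85):
        self.r_threshold = r_threshold

    def fit(self, X, y=None):
        if isinstance(X, ExpressionMatrix):
            matrix = X
        elif isinstance(X, pd.DataFrame):
            matrix = ExpressionMatrix(
                gene_ids=list(map(str, X.columns)),
                sample_ids=list(map(str, X.index)),
                values=X.to_numpy(dtype=np.float64).T,
            )
        else:
            X = np.asarray(X, dtype=np.float64)
            matrix = ExpressionMatrix(
                gene_ids=[f"g{i}" for i in range(X.shape[1])],
                sample_ids=[f"s{i}" for i in range(X.shape[0])],
                values=X.T,
            )
        self.correlation_ = pearson_correlation_matrix(matrix)
        self.feature_names_in_ = np.asarray(matrix.gene_ids, dtype=object)
        self.n_features_in_ = matrix.n_genes
        return self

    def network(self, r_threshold: Optional[float] = None) -> RegulatoryNetwork:
        if not hasattr(self, "correlation_"):
            raise InvalidInputError("estimator is not fitted")
        thr = self.r_threshold if r_threshold is None else r_threshold
        return relevance_network(self.correlation_, thr)
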