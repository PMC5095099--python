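"""Differential-gene detection from network degree changes.

The degree-difference ratio of a gene between two condition networks is

    eta = (|Ti - Ti'| + |To - To'|) / ((Ti + To) + (Ti' + To'))

with Ti/To the gene's directed in/out degrees in the first network and
Ti'/To' in the second.  eta is 0 for unchanged degrees, 1 when all degree
mass appears in only one of the networks, and 0 by convention for a gene
isolated in both.  Genes are ranked by descending eta; a configurable cutoff
(minimum eta or top-k) turns each two-condition ranking into a candidate set,
and candidate sets from several comparisons are combined by union or
intersection.

A conventional comparator — per-gene log2 fold change of group means with a
two-sample z-test — and a Venn-style overlap report complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .errors import InvalidInputError
from .matrix import ExpressionMatrix
from .network import RegulatoryNetwork

__all__ = [
    "DegreeRecord",
    "DegComparison",
    "FoldChangeRecord",
    "OverlapReport",
    "degree_difference_ratio",
    "rank_by_eta",
    "select_network_degs",
    "fold_change_z_test",
    "overlap_report",
]


@dataclass(frozen=True)
class DegreeRecord:
    """Directed in/out degrees of one gene in one network."""

    gene: str
    in_degree: int
    out_degree: int

    def __post_init__(self) -> None:
        if self.in_degree < 0 or self.out_degree < 0:
            raise InvalidInputError("degrees must be non-negative")


@dataclass
class DegComparison:
    """Per-gene degree comparison between two networks."""

    gene: str
    degrees_a: DegreeRecord
    degrees_b: DegreeRecord
    eta: float
    rank: int = 0


@dataclass
class FoldChangeRecord:
    """Per-gene fold-change/z-test result."""

    gene: str
    log2_fold_change: float
    z_statistic: float
    p_value: float
    is_deg: bool


@dataclass
class OverlapReport:
    """Venn counts (and memberships) of two candidate sets in a universe."""

    only_network: int
    only_fold_change: int
    both: int
    neither: int
    network_genes: list[str]
    fold_change_genes: list[str]
    both_genes: list[str]
    neither_genes: list[str]


def degree_difference_ratio(a: DegreeRecord, b: DegreeRecord) -> float:
    """eta for one gene; 0 when the gene is isolated in both networks."""
    num = abs(a.in_degree - b.in_degree) + abs(a.out_degree - b.out_degree)
    den = (a.in_degree + a.out_degree) + (b.in_degree + b.out_degree)
    return num / den if den else 0.0


def rank_by_eta(network_a: RegulatoryNetwork, network_b: RegulatoryNetwork
                ) -> list[DegComparison]:
    """eta for every gene, sorted by descending eta (ties by gene id).

    Both networks must cover the same gene set.  Ranks are 1..n.
    """
    if set(network_a.gene_ids) != set(network_b.gene_ids):
        raise InvalidInputError("networks cover different gene sets")
    in_a, out_a = network_a.in_degrees(), network_a.out_degrees()
    in_b, out_b = network_b.in_degrees(), network_b.out_degrees()
    comps = []
    for gene in network_a.gene_ids:
        da = DegreeRecord(gene, in_a[gene], out_a[gene])
        db = DegreeRecord(gene, in_b[gene], out_b[gene])
        comps.append(DegComparison(gene=gene, degrees_a=da, degrees_b=db,
                                   eta=degree_difference_ratio(da, db)))
    comps.sort(key=lambda c: (-c.eta, c.gene))
    for rank, c in enumerate(comps, start=1):
        c.rank = rank
    return comps


def _select_one(ranking: Sequence[DegComparison],
                policy: Mapping[str, float]) -> set[str]:
    if set(policy.keys()) == {"eta_min"}:
        eta_min = float(policy["eta_min"])
        return {c.gene for c in ranking if c.eta > 0 and c.eta >= eta_min}
    if set(policy.keys()) == {"top_k"}:
        k = int(policy["top_k"])
        if k < 0 or k > len(ranking):
            raise InvalidInputError(f"top_k={k} outside 0..{len(ranking)}")
        return {c.gene for c in ranking[:k]}
    raise InvalidInputError("policy must be {'eta_min': x} or {'top_k': k}")


def select_network_degs(ranking_1: Sequence[DegComparison],
                        ranking_2: Sequence[DegComparison],
                        policy: Optional[Mapping[str, float]] = None,
                        combine: Literal["union", "intersection"] = "union"
                        ) -> set[str]:
    """Apply the cutoff policy to two eta rankings and combine the results.

    ``policy`` defaults to ``{"eta_min": 0.5}``; with an ``eta_min`` policy a
    gene is selected when ``eta >= eta_min`` and its degrees changed at all
    (eta > 0).  ``combine`` joins the two comparisons' candidate sets by
    union (default) or intersection.
    """
    if policy is None:
        policy = {"eta_min": 0.5}
    u1 = {c.gene for c in ranking_1}
    u2 = {c.gene for c in ranking_2}
    if u1 != u2:
        raise InvalidInputError("rankings cover different gene universes")
    if combine not in ("union", "intersection"):
        raise InvalidInputError("combine must be 'union' or 'intersection'")
    s1 = _select_one(ranking_1, policy)
    s2 = _select_one(ranking_2, policy)
    return (s1 | s2) if combine == "union" else (s1 & s2)


def fold_change_z_test(group_a: ExpressionMatrix, group_b: ExpressionMatrix,
                       fc_threshold: float = 0.05, p_threshold: float = 0.05,
                       pseudocount: float = 1e-6) -> list[FoldChangeRecord]:
    """Per-gene log2 fold change (b over a) with a two-sample z-test.

    log2FC uses group means with a fixed pseudocount added to both (unit-
    scaled expression can have zero means); the z statistic is
    ``(mean_b - mean_a) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with sample
    variances, two-sided p from the standard normal.  A gene is flagged a
    DEG when ``|log2FC| >= fc_threshold`` (inclusive) and
    ``p < p_threshold``.
    """
    if group_a.gene_ids != group_b.gene_ids:
        if set(group_a.gene_ids) != set(group_b.gene_ids):
            raise InvalidInputError("groups cover different gene sets")
        reorder = [group_b.gene_index(g) for g in group_a.gene_ids]
        group_b = group_b.with_values(group_b.values[reorder])
        group_b = ExpressionMatrix(list(group_a.gene_ids),
                                   group_b.sample_ids, group_b.values,
                                   group_b.group)
    for g, name in ((group_a, "a"), (group_b, "b")):
        if g.n_samples < 2:
            raise InvalidInputError(f"group {name} needs >= 2 samples")
    ma = group_a.values.mean(axis=1)
    mb = group_b.values.mean(axis=1)
    va = group_a.values.var(axis=1, ddof=1)
    vb = group_b.values.var(axis=1, ddof=1)
    na, nb = group_a.n_samples, group_b.n_samples
    log2fc = np.log2((mb + pseudocount) / (ma + pseudocount))
    se = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (mb - ma) / np.where(se == 0, 1.0, se),
                     np.where(mb == ma, 0.0, np.inf * np.sign(mb - ma)))
    p = 2.0 * norm.sf(np.abs(z))
    records = []
    for i, gene in enumerate(group_a.gene_ids):
        is_deg = (abs(log2fc[i]) >= fc_threshold) and (p[i] < p_threshold)
        records.append(FoldChangeRecord(
            gene=gene, log2_fold_change=float(log2fc[i]),
            z_statistic=float(z[i]), p_value=float(p[i]), is_deg=bool(is_deg),
        ))
    return records


def overlap_report(network_degs: Iterable[str], fold_change_degs: Iterable[str],
                   universe: Iterable[str]) -> OverlapReport:
    """Venn counts of the two candidate sets within the gene universe."""
    net = set(network_degs)
    fc = set(fold_change_degs)
    uni = set(universe)
    if not net <= uni:
        raise InvalidInputError("network DEGs not contained in universe")
    if not fc <= uni:
        raise InvalidInputError("fold-change DEGs not contained in universe")
    both = net & fc
    only_net = net - fc
    only_fc = fc - net
    neither = uni - net - fc
    return OverlapReport(
        only_network=len(only_net), only_fold_change=len(only_fc),
        both=len(both), neither=len(neither),
        network_genes=sorted(only_net), fold_change_genes=sorted(only_fc),
        both_genes=sorted(both), neither_genes=sorted(neither),
    )
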