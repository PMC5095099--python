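"""Synthetic expression data with a planted regulatory structure.

The generator mirrors the model's own generative assumption: a regulated
gene's value is the sigmoid of a linear combination of its regulators minus a
threshold.  To keep the system acyclic and well-defined, a configurable
fraction of genes act as exogenous *drivers* whose values are drawn uniformly
on [0, 1] per sample; every remaining gene draws a random set of driver
regulators (expected size ``avg_regulators``) and is computed as

    x_j = sigmoid(sum_i W[i, j] * x_i - bias) + noise,   clipped to [0, 1].

With ``noise_sd = 0`` every regulated gene satisfies the sigmoid relation
exactly, so the data are a realisable instance of the inference model.  Note
the flip side: the drivers themselves carry the independent variation that
makes the planted edges identifiable, and are by construction *not* sigmoid
functions of the other genes — no regressor can fit them to low error.

:func:`recovery_metrics` scores an inferred network against the planted
truth (directed-edge precision/recall and sign accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .errors import InvalidInputError
from .matrix import ExpressionMatrix
from .network import RegulatoryNetwork

__all__ = [
    "PlantedGRN",
    "RecoveryMetrics",
    "generate_planted_grn",
    "rewire_gene",
    "simulate_expression",
    "recovery_metrics",
]


@dataclass
class PlantedGRN:
    """Ground-truth regulatory structure for simulation.

    ``true_weights[i, j]`` is the planted signed influence of gene i on gene
    j (zero diagonal); ``driver_ids`` are the exogenous genes with no
    incoming planted edges.
    """

    gene_ids: list[str]
    true_weights: np.ndarray
    bias: float
    sign_mix: float
    driver_ids: list[str]

    def __post_init__(self) -> None:
        self.true_weights = np.asarray(self.true_weights, dtype=np.float64)
        n = len(self.gene_ids)
        if self.true_weights.shape != (n, n):
            raise InvalidInputError(f"true_weights must be {n}x{n}")
        if np.any(np.diag(self.true_weights) != 0.0):
            raise InvalidInputError("true_weights must have a zero diagonal")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def true_edges(self) -> set[tuple[str, str]]:
        src, tgt = np.nonzero(self.true_weights)
        return {(self.gene_ids[i], self.gene_ids[j])
                for i, j in zip(src.tolist(), tgt.tolist())}


@dataclass
class RecoveryMetrics:
    """Directed-edge recovery scores; ``None`` marks undefined ratios
    (no inferred edges for precision, no true positives for sign accuracy)."""

    precision: Optional[float]
    recall: Optional[float]
    sign_accuracy: Optional[float]
    n_true_edges: int
    n_inferred_edges: int
    n_true_positives: int


def generate_planted_grn(n_genes: int, avg_regulators: float = 2.0,
                         sign_mix: float = 0.3, weight_scale: float = 2.0,
                         seed: int = 0, driver_fraction: float = 0.5,
                         bias: float = -1.0, gene_prefix: str = "G"
                         ) -> PlantedGRN:
    """Draw a random two-tier planted network.

    The first ``round(driver_fraction * n_genes)`` genes (at least one, at
    most ``n_genes - 1``) are exogenous drivers.  Each remaining gene draws a
    regulator set from the drivers with expected size *avg_regulators*
    (stochastic rounding of the fractional part), weight magnitudes uniform
    on ``[0.5, 1.5] * weight_scale``, negative with probability *sign_mix*.
    Deterministic for a given seed.
    """
    if n_genes < 2:
        raise InvalidInputError("n_genes must be >= 2")
    if not 0.0 <= sign_mix <= 1.0:
        raise InvalidInputError("sign_mix must be in [0, 1]")
    if avg_regulators < 0 or avg_regulators >= n_genes:
        raise InvalidInputError("avg_regulators must be in [0, n_genes)")
    n_drivers = int(round(driver_fraction * n_genes))
    n_drivers = min(max(n_drivers, 1), n_genes - 1)
    if np.ceil(avg_regulators) > n_drivers:
        raise InvalidInputError(
            f"cannot draw ~{avg_regulators} distinct regulators from "
            f"{n_drivers} driver genes"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_genes - 1))
    gene_ids = [f"{gene_prefix}{i:0{width}d}" for i in range(n_genes)]
    W = np.zeros((n_genes, n_genes))
    base = int(np.floor(avg_regulators))
    frac = avg_regulators - base
    for j in range(n_drivers, n_genes):
        k = base + (1 if rng.random() < frac else 0)
        if k == 0:
            continue
        regs = rng.choice(n_drivers, size=k, replace=False)
        for i in regs:
            mag = weight_scale * rng.uniform(0.5, 1.5)
            sgn = -1.0 if rng.random() < sign_mix else 1.0
            W[i, j] = sgn * mag
    return PlantedGRN(gene_ids=gene_ids, true_weights=W, bias=bias,
                      sign_mix=sign_mix, driver_ids=gene_ids[:n_drivers])


def rewire_gene(grn: PlantedGRN, gene: str, seed: int = 0,
                n_new: Optional[int] = None) -> PlantedGRN:
    """Return a copy of the planted network with *gene*'s regulators redrawn.

    The gene's incoming edges are replaced by a freshly drawn driver set of
    size *n_new* (default: the original count, with the new set guaranteed
    different whenever an alternative exists).  ``n_new=0`` knocks the
    gene's regulation out entirely, which makes it a maximally differential
    gene by degree between the two planted networks.
    """
    if gene not in grn.gene_ids:
        raise InvalidInputError(f"gene {gene!r} not in network")
    if gene in grn.driver_ids:
        raise InvalidInputError(f"gene {gene!r} is an exogenous driver and "
                                "has no regulators to rewire")
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(grn.gene_ids)}
    j = idx[gene]
    n_drivers = len(grn.driver_ids)
    old = frozenset(np.nonzero(grn.true_weights[:, j])[0].tolist())
    k = len(old) if n_new is None else int(n_new)
    if k < 0 or k > n_drivers:
        raise InvalidInputError(f"cannot draw {k} distinct regulators from "
                                f"{n_drivers} drivers")
    W = grn.true_weights.copy()
    W[:, j] = 0.0
    if k == 0:
        new: frozenset[int] = frozenset()
    else:
        new = old
        for _ in range(1000):
            new = frozenset(
                rng.choice(n_drivers, size=k, replace=False).tolist())
            if new != old:
                break
    scale = (np.abs(grn.true_weights[list(old), j]).mean()
             if old else 1.0)
    for i in new:
        sgn = -1.0 if rng.random() < grn.sign_mix else 1.0
        W[i, j] = sgn * scale * rng.uniform(0.5, 1.5)
    return PlantedGRN(gene_ids=list(grn.gene_ids), true_weights=W,
                      bias=grn.bias, sign_mix=grn.sign_mix,
                      driver_ids=list(grn.driver_ids))


def simulate_expression(grn: PlantedGRN, n_samples: int, noise_sd: float = 0.0,
                        seed: int = 0, group: Optional[str] = None
                        ) -> ExpressionMatrix:
    """Simulate a genes x samples matrix from the planted structure.

    Driver genes are uniform on [0, 1]; each regulated gene is the sigmoid of
    its planted weighted input minus the threshold, plus optional Gaussian
    noise, clipped to [0, 1].  Deterministic for a given seed.
    """
    if n_samples < 1:
        raise InvalidInputError("n_samples must be >= 1")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = grn.n_genes
    n_drivers = len(grn.driver_ids)
    X = np.zeros((n, n_samples))
    X[:n_drivers] = rng.uniform(0.0, 1.0, size=(n_drivers, n_samples))
    for j in range(n_drivers, n):
        X[j] = expit(grn.true_weights[:, j] @ X - grn.bias)
    if noise_sd > 0:
        X[n_drivers:] += rng.normal(0.0, noise_sd,
                                    size=(n - n_drivers, n_samples))
        np.clip(X, 0.0, 1.0, out=X)
    sample_ids = [f"s{p}" for p in range(n_samples)]
    return ExpressionMatrix(gene_ids=list(grn.gene_ids),
                            sample_ids=sample_ids, values=X, group=group)


def recovery_metrics(truth: PlantedGRN, inferred: RegulatoryNetwork
                     ) -> RecoveryMetrics:
    """Score inferred directed edges against the planted support.

    Precision is ``None`` when nothing was inferred; recall is ``None`` when
    the truth has no edges; sign accuracy (fraction of true positives whose
    inferred sign matches the planted weight's sign) is ``None`` without true
    positives.
    """
    if set(truth.gene_ids) != set(inferred.gene_ids):
        raise InvalidInputError("truth and inferred networks cover different "
                                "gene sets")
    true_edges = truth.true_edges()
    inferred_pairs = inferred.edge_pairs()
    tp_pairs = true_edges & inferred_pairs
    idx = {g: i for i, g in enumerate(truth.gene_ids)}
    sign_ok = 0
    for e in inferred.edges:
        if (e.source, e.target) in true_edges:
            tw = truth.true_weights[idx[e.source], idx[e.target]]
            if np.sign(e.weight) == np.sign(tw):
                sign_ok += 1
    precision = len(tp_pairs) / len(inferred_pairs) if inferred_pairs else None
    recall = len(tp_pairs) / len(true_edges) if true_edges else None
    sign_accuracy = sign_ok / len(tp_pairs) if tp_pairs else None
    return RecoveryMetrics(
        precision=precision, recall=recall, sign_accuracy=sign_accuracy,
        n_true_edges=len(true_edges), n_inferred_edges=len(inferred_pairs),
        n_true_positives=len(tp_pairs),
    )
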