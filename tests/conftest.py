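"""Shared fixtures: tiny hand-built matrices/networks and the (expensive)
planted-network recovery run, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bpgrn import (
    Edge,
    ExpressionMatrix,
    PipelineConfig,
    RegulatoryNetwork,
    TrainingConfig,
    build_network,
    generate_planted_grn,
    run_pipeline,
    simulate_expression,
    train_all_regressors,
)
from bpgrn._rng import substream_seed
from bpgrn.io import write_expression_tsv

#: Fixed seed of the session-scoped recovery experiment.
RECOVERY_SEED = 7


def make_network(gene_ids, pairs, threshold=0.0, method="bp",
                 weights=None) -> RegulatoryNetwork:
    """Build a network from (source, target) pairs with unit weights."""
    edges = []
    for k, (s, t) in enumerate(pairs):
        w = 1.0 if weights is None else weights[k]
        edges.append(Edge(s, t, w, abs(w),
                          "activation" if w > 0 else "inhibition"))
    return RegulatoryNetwork(gene_ids=list(gene_ids), edges=edges,
                             threshold_used=threshold, method=method)


def make_undirected(gene_ids, pairs, **kw) -> RegulatoryNetwork:
    """Symmetric directed encoding of an undirected edge list."""
    sym = []
    for s, t in pairs:
        sym.append((s, t))
        sym.append((t, s))
    return make_network(gene_ids, sym, **kw)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array([
            [2.0, 4.0, 6.0, 4.0],
            [0.3, 0.3, 0.3, 0.3],
            [0.0, 1.0, 0.5, 0.25],
        ]),
    )


@pytest.fixture(scope="session")
def recovery_run():
    """20-gene planted network, 200 noiseless samples, full BP training.

    The study conditions of the end-to-end recovery check: 10 exogenous
    driver genes, 10 regulated genes with 2 planted regulators each,
    default training configuration, evaluation threshold lambda = 0.2
    (40% of the ideal per-edge incoming ratio 1/2, ~4x the uninformative
    level 1/19).
    """
    grn = generate_planted_grn(
        20, avg_regulators=2.0, sign_mix=0.3, weight_scale=2.0,
        driver_fraction=0.5, seed=substream_seed(RECOVERY_SEED, "grn"))
    matrix = simulate_expression(
        grn, 200, noise_sd=0.0, seed=substream_seed(RECOVERY_SEED, "expression"))
    wm = train_all_regressors(
        matrix, TrainingConfig(seed=substream_seed(RECOVERY_SEED, "train")))
    net = build_network(wm, threshold=0.2)
    return grn, matrix, wm, net


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The full pipeline executed twice with identical config and seed
    on a small two-condition synthetic dataset."""
    root = tmp_path_factory.mktemp("pipeline")
    grn = generate_planted_grn(10, seed=21)
    for name, s in (("A", 31), ("B", 32)):
        m = simulate_expression(grn, 60, noise_sd=0.03, seed=s, group=name)
        # shift/scale away from [0, 1] so normalization has work to do
        write_expression_tsv(m.with_values(m.values * 120.0 + 3.0),
                             root / f"{name}.tsv")
    outs = []
    for run_dir in ("run1", "run2"):
        cfg = PipelineConfig(
            groups={"A": str(root / "A.tsv"), "B": str(root / "B.tsv")},
            reference="A", out_dir=str(root / run_dir), seed=5,
            max_cycles=300, thresholds=(0.3, 0.5, 0.85), deg_threshold=0.3,
            eta_min=0.5)
        run_pipeline(cfg)
        outs.append(root / run_dir)
    return outs
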