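"""End-to-end pipeline: expression TSVs in, network/DEG artifacts out.

Stages, in order, per condition group: read -> normalize -> block-average ->
train per-gene regressors -> threshold sweep networks -> topology stats ->
Pearson relevance baseline.  Then, across groups: parameter comparison table
against the reference condition, eta rankings and network DEG selection,
the fold-change/z-test comparator, and the overlap report.  Every stage's
outputs are plain text (TSV/JSON), re-readable by the package's own readers,
and a run manifest records the config echo, seed, library versions and the
status of every stage, so a run can be reproduced exactly.

All randomness derives from the single top-level seed through named
substreams (one per stage), so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream_seed
from .bp import TrainingConfig, train_all_regressors
from .deg import _select_one, fold_change_z_test, overlap_report, rank_by_eta
from .errors import GrnError, InvalidInputError
from .io import (
    read_expression_tsv,
    write_edge_list_tsv,
    write_expression_tsv,
    write_graphml,
    write_json,
    write_stats_json,
    write_weight_matrix_tsv,
    write_weight_metadata_json,
)
from .network import DEFAULT_THRESHOLDS, build_network, sweep_thresholds
from .preprocess import block_average, normalize_expression
from .relevance import (
    pearson_correlation_matrix,
    relevance_network,
    zero_degree_count,
)
from .stats import compare_stats, compute_stats

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("bpgrn")


class PipelineError(GrnError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run.

    ``groups`` maps condition labels to expression TSV paths; ``reference``
    names the condition the others are compared against (defaults to the
    first group).  The remaining fields mirror the stage parameters.
    """

    groups: dict[str, str]
    reference: Optional[str] = None
    out_dir: str = "bpgrn_out"
    seed: int = 0
    normalization_scope: str = "per_gene"
    block_size: int = 2
    learning_rate: float = 0.7
    momentum: float = 0.5
    bias: float = -1.0
    max_cycles: int = 1000
    error_tolerance: float = 1e-2
    init_scale: float = 0.1
    bias_trainable: bool = False
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    deg_threshold: float = 0.85
    r_threshold: float = 0.85
    eta_min: Optional[float] = 0.5
    top_k: Optional[int] = None
    deg_combine: str = "union"
    fc_threshold: float = 0.05
    p_threshold: float = 0.05
    pseudocount: float = 1e-6
    graphml: bool = False

    def __post_init__(self) -> None:
        if not self.groups:
            raise InvalidInputError("at least one condition group is required")
        self.groups = {str(k): str(v) for k, v in self.groups.items()}
        if self.reference is None:
            self.reference = next(iter(self.groups))
        if self.reference not in self.groups:
            raise InvalidInputError(
                f"reference {self.reference!r} is not a group"
            )
        self.thresholds = tuple(float(t) for t in self.thresholds)
        for t in self.thresholds + (self.deg_threshold, self.r_threshold):
            if not 0.0 <= t <= 1.0:
                raise InvalidInputError(f"threshold {t} outside [0, 1]")
        if self.eta_min is not None and self.top_k is not None:
            raise InvalidInputError("give eta_min or top_k, not both")

    @property
    def deg_policy(self) -> dict[str, float]:
        if self.top_k is not None:
            return {"top_k": self.top_k}
        return {"eta_min": self.eta_min if self.eta_min is not None else 0.5}

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate, momentum=self.momentum,
            bias=self.bias, max_cycles=self.max_cycles,
            error_tolerance=self.error_tolerance, init_scale=self.init_scale,
            seed=substream_seed(self.seed, "train"),
            bias_trainable=self.bias_trainable,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _fmt_thr(thr: float) -> str:
    return f"{thr:.2f}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "bpgrn": __version__,
            "numpy": np.__version__,
        },
        "stages": {},
        "artifacts": [],
    }

    def artifact(path: Path) -> Path:
        manifest["artifacts"].append(str(path.relative_to(out)))
        return path

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = f"failed: {exc}"
        write_json(manifest, out / "manifest.json")
        raise PipelineError(stage, str(exc)) from exc

    matrices = {}
    networks_by_group: dict[str, list] = {}
    stats_by_group: dict[str, list] = {}
    deg_networks = {}
    gene_ids: Optional[list[str]] = None
    stats_seed = substream_seed(config.seed, "stats")

    for group, path in config.groups.items():
        gdir = out / group
        gdir.mkdir(exist_ok=True)
        stage = f"preprocess[{group}]"
        try:
            matrix = read_expression_tsv(path, group=group)
            matrix = normalize_expression(matrix, config.normalization_scope)
            matrix = block_average(matrix, config.block_size)
            write_expression_tsv(matrix, artifact(gdir / "preprocessed.tsv"))
            if gene_ids is None:
                gene_ids = list(matrix.gene_ids)
            elif gene_ids != matrix.gene_ids:
                raise InvalidInputError(
                    f"group {group!r} has a different gene list"
                )
            matrices[group] = matrix
        except Exception as exc:
            fail(stage, exc)
        manifest["stages"][stage] = "ok"

        stage = f"train[{group}]"
        try:
            wm = train_all_regressors(matrix, config.training_config())
            write_weight_matrix_tsv(wm, artifact(gdir / "weights.tsv"))
            write_weight_metadata_json(
                wm, artifact(gdir / "weights_meta.json"))
            n_conv = int(np.sum(wm.converged))
            logger.info("group %s: %d/%d regressors converged",
                        group, n_conv, wm.n_genes)
            manifest.setdefault("convergence", {})[group] = {
                "n_converged": n_conv, "n_genes": wm.n_genes,
            }
        except Exception as exc:
            fail(stage, exc)
        manifest["stages"][stage] = "ok"

        stage = f"networks[{group}]"
        try:
            nets = sweep_thresholds(wm, config.thresholds)
            networks_by_group[group] = nets
            stats_list = []
            for thr, net in zip(config.thresholds, nets):
                write_edge_list_tsv(
                    net, artifact(gdir / f"edges_bp_{_fmt_thr(thr)}.tsv"))
                if config.graphml:
                    write_graphml(
                        net, artifact(gdir / f"network_{_fmt_thr(thr)}.graphml"))
                st = compute_stats(net, seed=stats_seed)
                stats_list.append(st)
                logger.info("group %s thr %.2f: %d edges",
                            group, thr, net.n_edges)
            write_stats_json(stats_list, artifact(gdir / "stats_bp.json"))
            stats_by_group[group] = list(zip(config.thresholds, stats_list))
            deg_networks[group] = build_network(
                wm, threshold=config.deg_threshold)
        except Exception as exc:
            fail(stage, exc)
        manifest["stages"][stage] = "ok"

        stage = f"baseline[{group}]"
        try:
            corr = pearson_correlation_matrix(matrix)
            rel = relevance_network(corr, config.r_threshold)
            write_edge_list_tsv(rel, artifact(gdir / "edges_pearson.tsv"))
            rel_stats = compute_stats(rel, seed=stats_seed)
            write_stats_json(rel_stats, artifact(gdir / "stats_pearson.json"),
                             method="pearson")
            manifest.setdefault("baseline", {})[group] = {
                "zero_degree_genes": zero_degree_count(rel),
                "n_genes": rel.n_nodes,
            }
        except Exception as exc:
            fail(stage, exc)
        manifest["stages"][stage] = "ok"

    comparisons = [g for g in config.groups if g != config.reference]

    if comparisons:
        stage = "compare_stats"
        try:
            table = compare_stats(stats_by_group, config.reference)
            table.to_csv(artifact(out / "comparison_stats.tsv"), sep="\t",
                         index=False)
        except Exception as exc:
            fail(stage, exc)
        manifest["stages"][stage] = "ok"

        stage = "deg"
        try:
            degdir = out / "deg"
            degdir.mkdir(exist_ok=True)
            rankings = {}
            for cond in comparisons:
                ranking = rank_by_eta(deg_networks[cond],
                                      deg_networks[config.reference])
                rankings[cond] = ranking
                rows = []
                for c in ranking:
                    rows.append({
                        "gene": c.gene,
                        "in_degree_a": c.degrees_a.in_degree,
                        "out_degree_a": c.degrees_a.out_degree,
                        "in_degree_b": c.degrees_b.in_degree,
                        "out_degree_b": c.degrees_b.out_degree,
                        "eta": c.eta, "rank": c.rank,
                        "selected": c.gene in _select_one(
                            ranking, config.deg_policy),
                    })
                pd.DataFrame(rows).to_csv(
                    artifact(degdir / f"eta_{cond}_vs_{config.reference}.tsv"),
                    sep="\t", index=False)
            sel_sets = [_select_one(r, config.deg_policy)
                        for r in rankings.values()]
            if config.deg_combine == "union":
                network_degs = set().union(*sel_sets)
            elif config.deg_combine == "intersection":
                network_degs = set.intersection(*sel_sets)
            else:
                raise InvalidInputError(
                    f"deg_combine must be union or intersection, got "
                    f"{config.deg_combine!r}")

            fc_sets = []
            for cond in comparisons:
                records = fold_change_z_test(
                    matrices[config.reference], matrices[cond],
                    fc_threshold=config.fc_threshold,
                    p_threshold=config.p_threshold,
                    pseudocount=config.pseudocount)
                pd.DataFrame(
                    [dataclasses.asdict(r) for r in records]).to_csv(
                    artifact(degdir /
                             f"fold_change_{cond}_vs_{config.reference}.tsv"),
                    sep="\t", index=False)
                fc_sets.append({r.gene for r in records if r.is_deg})
            if config.deg_combine == "union":
                fc_degs = set().union(*fc_sets)
            else:
                fc_degs = set.intersection(*fc_sets)

            report = overlap_report(network_degs, fc_degs, set(gene_ids))
            write_json({
                "only_network": report.only_network,
                "only_fold_change": report.only_fold_change,
                "both": report.both,
                "neither": report.neither,
                "network_genes": report.network_genes,
                "fold_change_genes": report.fold_change_genes,
                "both_genes": report.both_genes,
                "pseudocount": config.pseudocount,
            }, artifact(degdir / "venn.json"))
        except Exception as exc:
            fail(stage, exc)
        manifest["stages"][stage] = "ok"

    write_json(manifest, out / "manifest.json")
    return manifest
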