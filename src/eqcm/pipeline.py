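"""End-to-end orchestration: network, mining, survival screen, thresholds,
selection, clustering, representatives — plus the stage outputs on disk."""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import io as eio
from .miner import MinerConfig, beta_merge, expand_all_seeds
from .network import ExpressionMatrix, SubNetwork, WeightedNetwork, build_wgcn
from .significance import (
    ClusterGroup,
    ThresholdTable,
    build_threshold_table,
    merge_into_clusters,
    select_significant,
    size_bin,
)
from .survival import (
    ClinicalTable,
    SurvivalTestResult,
    derive_seed,
    km_curve,
    subnetwork_survival_test,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run", "run_pipeline"]

#: above this many genes the dense network and per-set screens get slow on a
#: laptop; the pipeline warns but proceeds.
GENE_COUNT_WARNING = 5000


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; defaults follow the reference
    workflow (gamma=0.7, lambda=1, t=1, beta=0.99999, >=10 genes, K=2 with
    100 restarts, 1000 random tests, lower 5th percentile, >50% overlap)."""

    miner: MinerConfig = field(default_factory=MinerConfig)
    kmeans_replicates: int = 100
    n_random: int = 1000
    percentile: float = 0.05
    r_cutoff: float = 0.5
    master_seed: int = 0
    expression_path: Optional[str] = None
    clinical_path: Optional[str] = None
    out_dir: Optional[str] = None


@dataclass
class PipelineResult:
    network: WeightedNetwork
    subnetworks_raw: List[SubNetwork]
    subnetworks: List[SubNetwork]
    survival_results: Dict[str, SurvivalTestResult]
    threshold_table: ThresholdTable
    significant: List[SubNetwork]
    clusters: List[ClusterGroup]
    report: Dict


def run(expr: ExpressionMatrix, clin: ClinicalTable, cfg: PipelineConfig) -> PipelineResult:
    """Run every stage in memory and return all intermediates plus a report.

    All stochastic stages (K-means restarts, random gene lists) derive their
    seeds from ``cfg.master_seed``; the report echoes the config, per-stage
    counts, derived seeds and wall-clock seconds.
    """
    timings: Dict[str, float] = {}
    counts: Dict[str, int] = {}

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = _time.perf_counter()
                return self

            def __exit__(self, *exc):
                timings[name] = round(_time.perf_counter() - self.t0, 4)
                log.info("stage %s finished in %.2fs", name, timings[name])
                return False

        return _T()

    if expr.n_genes > GENE_COUNT_WARNING:
        log.warning(
            "%d genes: the dense network will be large; expect a long run",
            expr.n_genes,
        )

    with _stage("build_network"):
        net = build_wgcn(expr)
    counts["genes"] = net.n_vertices
    counts["samples"] = expr.n_samples

    with _stage("mine"):
        raw = expand_all_seeds(net, cfg.miner)
        merged = beta_merge(raw, cfg.miner.beta, net)
        subs = [s for s in merged if s.size >= cfg.miner.min_size]
        for k, s in enumerate(subs):
            s.id = f"M{k + 1:04d}"
    counts["subnetworks_raw"] = len(raw)
    counts["subnetworks"] = len(subs)

    with _stage("survival_screen"):
        results: Dict[str, SurvivalTestResult] = {}
        for s in subs:
            res = subnetwork_survival_test(
                s,
                expr,
                clin,
                rng_seed=derive_seed(cfg.master_seed, f"survival-{s.id}"),
                replicates=cfg.kmeans_replicates,
            )
            s.pvalue = res.pvalue
            results[s.id] = res
    counts["survival_tests"] = len(results)

    with _stage("thresholds"):
        bins = sorted({size_bin(s.size) for s in subs})
        table = build_threshold_table(
            expr,
            clin,
            bins=bins,
            n_random=cfg.n_random,
            rng_seed=derive_seed(cfg.master_seed, "thresholds"),
            replicates=cfg.kmeans_replicates,
            percentile=cfg.percentile,
        ) if bins else ThresholdTable({}, n_random=cfg.n_random, seed=0)
    counts["threshold_bins"] = len(table.thresholds)

    with _stage("select"):
        significant = select_significant(subs, table)
    counts["significant"] = len(significant)

    with _stage("cluster"):
        clusters = merge_into_clusters(significant, cfg.r_cutoff)
    counts["clusters"] = len(clusters)

    report = {
        "config": {
            "miner": dataclasses.asdict(cfg.miner),
            "kmeans_replicates": cfg.kmeans_replicates,
            "n_random": cfg.n_random,
            "percentile": cfg.percentile,
            "r_cutoff": cfg.r_cutoff,
            "master_seed": cfg.master_seed,
        },
        "counts": counts,
        "seeds": {
            "thresholds": derive_seed(cfg.master_seed, "thresholds"),
            "survival": {
                s.id: derive_seed(cfg.master_seed, f"survival-{s.id}") for s in subs
            },
        },
        "thresholds": {str(b): table.thresholds[b] for b in table.bins},
        "representatives": [c.representative.id for c in clusters],
        "timings_seconds": timings,
    }
    return PipelineResult(
        network=net,
        subnetworks_raw=raw,
        subnetworks=subs,
        survival_results=results,
        threshold_table=table,
        significant=significant,
        clusters=clusters,
        report=report,
    )


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """File-to-file run: read inputs, run all stages, write stage outputs.

    Writes into ``cfg.out_dir``: the network edge list, mined sub-networks
    (GMT), survival results (TSV), the threshold table (TSV + JSON sidecar),
    significant sub-networks and cluster representatives (GMT), the cluster
    table, Kaplan-Meier coordinates for each representative, and report.json.
    Returns the report dict.
    """
    if not (cfg.expression_path and cfg.clinical_path and cfg.out_dir):
        raise ValueError("expression_path, clinical_path and out_dir are required")
    expr = eio.read_expression(cfg.expression_path)
    clin = eio.read_clinical(cfg.clinical_path)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    res = run(expr, clin, cfg)

    eio.write_edge_list(res.network, out / "network_edges.tsv")
    eio.write_gmt(res.subnetworks, out / "subnetworks.gmt")
    eio.write_results(
        [(s, res.survival_results[s.id]) for s in res.subnetworks],
        out / "survival_results.tsv",
    )
    eio.write_threshold_table(res.threshold_table, out / "thresholds.tsv")
    eio.write_gmt(res.significant, out / "significant.gmt")
    eio.write_clusters(res.clusters, out / "clusters.tsv")
    eio.write_gmt([c.representative for c in res.clusters], out / "representatives.gmt")

    curves: Dict[str, Dict[int, tuple]] = {}
    for c in res.clusters:
        rep = c.representative
        tres = res.survival_results[rep.id]
        t, e = clin.subset(tres.sample_ids)
        curves[rep.id] = {}
        for grp in (0, 1):
            mask = tres.group_labels == grp
            curves[rep.id][grp] = km_curve(t[mask], e[mask])
    eio.write_km_curves(curves, out / "km_curves.tsv")

    with open(out / "report.json", "w") as fh:
        json.dump(res.report, fh, indent=1, sort_keys=True)
    return res.report
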