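"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and clinical tables are tab-delimited text; gene sets
travel as GMT lines (id, description, then member genes); networks as
3-column edge lists; thresholds as a two-column TSV with a JSON sidecar.
All formats round-trip exactly except the edge list, whose weights are
printed with 8 significant digits.
"""

from __future__ import annotations

import json
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import ExpressionMatrix, SubNetwork, WeightedNetwork
from .significance import ClusterGroup, ThresholdTable
from .survival import ClinicalTable, SurvivalTestResult

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "write_edge_list",
    "read_edge_list",
    "write_gmt",
    "read_gmt",
    "write_results",
    "read_results",
    "write_threshold_table",
    "read_threshold_table",
    "write_clusters",
    "write_km_curves",
]

VALID_STATUS = {"DECEASED": True, "LIVING": False}


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in {path} (e.g. gene {bad[0]!r})")
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], df.to_numpy(float)
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV.

    Accepts either ``sample_id, time_days, vital_status`` with status in
    {LIVING, DECEASED}, or pre-coded ``sample_id, time, event`` (event in
    {0,1,true,false}).  Rows with an invalid vital status are rejected with
    a line-numbered warning, mirroring a valid-vital-status filter.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ValueError(f"{path}: missing sample_id column")
    ids: List[str] = []
    times: List[float] = []
    events: List[bool] = []
    if "vital_status" in cols:
        tcol = cols.get("time_days") or cols.get("time")
        if tcol is None:
            raise ValueError(f"{path}: missing time_days column")
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            rec = dict(zip(df.columns, row))
            status = str(rec[cols["vital_status"]]).strip().upper()
            if status not in VALID_STATUS:
                warnings.warn(
                    f"{path}:{row_no}: invalid vital status {status!r}; row dropped",
                    stacklevel=2,
                )
                continue
            ids.append(str(rec[cols["sample_id"]]))
            times.append(float(rec[tcol]))
            events.append(VALID_STATUS[status])
    elif "event" in cols:
        tcol = cols.get("time") or cols.get("time_days")
        if tcol is None:
            raise ValueError(f"{path}: missing time column")
        truthy = {"1", "true", "t", "yes"}
        falsy = {"0", "false", "f", "no"}
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            rec = dict(zip(df.columns, row))
            ev = str(rec[cols["event"]]).strip().lower()
            if ev not in truthy | falsy:
                warnings.warn(
                    f"{path}:{row_no}: unreadable event flag {ev!r}; row dropped",
                    stacklevel=2,
                )
                continue
            ids.append(str(rec[cols["sample_id"]]))
            times.append(float(rec[tcol]))
            events.append(ev in truthy)
    else:
        raise ValueError(f"{path}: need vital_status or event column")
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids")
    return ClinicalTable(ids, np.array(times), np.array(events, dtype=bool))


def write_clinical(clin: ClinicalTable, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": clin.sample_ids,
            "time_days": clin.time,
            "vital_status": ["DECEASED" if e else "LIVING" for e in clin.event],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_edge_list(net: WeightedNetwork, path, min_weight: float = 0.0) -> None:
    """3-column edge list (gene_a, gene_b, weight) for all edges >= min_weight."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        n = net.n_vertices
        for i in range(n):
            for j in range(i + 1, n):
                w = net.weights[i, j]
                if w >= min_weight and w > 0.0:
                    a, b = net.vertices[i], net.vertices[j]
                    if b < a:
                        a, b = b, a
                    fh.write(f"{a}\t{b}\t{w:.8g}\n")


def read_edge_list(path) -> WeightedNetwork:
    """Rebuild a network from an edge list; absent pairs get weight 0."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    verts = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    idx = {v: i for i, v in enumerate(verts)}
    W = np.zeros((len(verts), len(verts)))
    for a, b, w in zip(df["gene_a"], df["gene_b"], df["weight"].astype(float)):
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return WeightedNetwork(verts, W)


def _describe(sub: SubNetwork) -> str:
    seed = ",".join(sub.seed_edge) if sub.seed_edge else ""
    p = "" if sub.pvalue is None else repr(sub.pvalue)
    return f"density={sub.density!r};seed={seed};pvalue={p}"


def write_gmt(subs: Sequence[SubNetwork], path) -> None:
    """One gene set per line: id, description, member genes, tab-delimited."""
    with open(path, "w") as fh:
        for s in subs:
            fh.write("\t".join([s.id, _describe(s), *s.sorted_members]) + "\n")


def read_gmt(path) -> List[SubNetwork]:
    subs: List[SubNetwork] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT line needs id, description and >= 1 gene"
                )
            sid, desc, genes = fields[0], fields[1], fields[2:]
            dens, seed, pval = float("nan"), None, None
            for part in desc.split(";"):
                if part.startswith("density=") and part[8:]:
                    dens = float(part[8:])
                elif part.startswith("seed=") and part[5:]:
                    seed = tuple(part[5:].split(","))
                elif part.startswith("pvalue=") and part[7:]:
                    pval = float(part[7:])
            subs.append(
                SubNetwork(
                    members=frozenset(genes),
                    density=dens,
                    seed_edge=seed,
                    pvalue=pval,
                    id=sid,
                )
            )
    return subs


def write_results(
    rows: Sequence[Tuple[SubNetwork, SurvivalTestResult]], path
) -> None:
    """Per-sub-network survival screen results as TSV."""
    recs = [
        {
            "id": sub.id,
            "size": sub.size,
            "density": sub.density,
            "chi_square": res.chi_square,
            "pvalue": res.pvalue,
            "n_group0": res.group_sizes[0],
            "n_group1": res.group_sizes[1],
        }
        for sub, res in rows
    ]
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def write_threshold_table(table: ThresholdTable, path) -> None:
    """Two-column TSV (bin, threshold) plus a JSON sidecar with the nulls."""
    with open(path, "w") as fh:
        fh.write("bin\tthreshold\n")
        for b in table.bins:
            fh.write(f"{b}\t{table.thresholds[b]!r}\n")
    sidecar = {
        "n_random": table.n_random,
        "seed": table.seed,
        "percentile": table.percentile,
        "pvalues": {str(b): list(v) for b, v in table.pvalues.items()},
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_threshold_table(path) -> ThresholdTable:
    df = pd.read_csv(path, sep="\t")
    thresholds = {int(b): float(t) for b, t in zip(df["bin"], df["threshold"])}
    n_random, seed, percentile, pvalues = 0, 0, 0.05, {}
    try:
        with open(str(path) + ".json") as fh:
            side = json.load(fh)
        n_random = int(side.get("n_random", 0))
        seed = int(side.get("seed", 0))
        percentile = float(side.get("percentile", 0.05))
        pvalues = {int(b): tuple(v) for b, v in side.get("pvalues", {}).items()}
    except FileNotFoundError:
        pass
    return ThresholdTable(
        thresholds=thresholds,
        n_random=n_random,
        seed=seed,
        percentile=percentile,
        pvalues=pvalues,
    )


def write_clusters(clusters: Sequence[ClusterGroup], path) -> None:
    recs = [
        {
            "cluster_id": f"C{k + 1:03d}",
            "n_members": c.size,
            "representative_id": c.representative.id,
            "representative_pvalue": c.representative.pvalue,
            "union_gene_count": len(c.union_genes),
        }
        for k, c in enumerate(clusters)
    ]
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def write_km_curves(
    curves: Dict[str, Dict[int, Tuple[np.ndarray, np.ndarray]]], path
) -> None:
    """Kaplan-Meier step coordinates, one row per (set, group, time) point."""
    with open(path, "w") as fh:
        fh.write("id\tgroup\ttime\tsurvival\n")
        for sid in sorted(curves):
            for grp in sorted(curves[sid]):
                times, surv = curves[sid][grp]
                for t, s in zip(times, surv):
                    fh.write(f"{sid}\t{grp}\t{t:.10g}\t{s:.10g}\n")
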