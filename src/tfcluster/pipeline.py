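"""End-to-end orchestration: load -> neighborhoods -> SCCM -> Triple-Link.

All artifacts are deterministic text files; rerunning the same
configuration (any worker count) reproduces them byte for byte, and
every number in the run log can be recomputed from the written tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import networkx as nx
import yaml

from .coexpression import AssociationParams, all_neighborhoods
from .io import ExpressionMatrix, TFSet, load_expression, load_tf_list, write_table
from .sccm import SCCM, build_sccm, connectivity_stats, export_sccm
from .triple_link import ClusteringResult, TripleLinkParams, decompose

__all__ = [
    "RunConfig",
    "validate_config",
    "run_pipeline",
    "write_neighborhoods",
    "write_clusters",
    "export_graphml",
]

log = logging.getLogger("tfcluster")


@dataclass(frozen=True)
class RunConfig:
    expression: str
    tfs: str
    out: str
    dialect: str = "tsv"
    missing: str = "error"
    assoc: AssociationParams = field(default_factory=AssociationParams)
    triple: TripleLinkParams = field(default_factory=TripleLinkParams)
    workers: int = 1
    log_level: str = "INFO"


# keys accepted in a flat key-value config file
_CONFIG_KEYS = {
    "expression", "tfs", "out", "dialect", "missing", "method", "omega",
    "min_samples", "direction", "theta1", "theta2", "theta3", "workers",
    "log_level",
}


def validate_config(raw: Union[str, Mapping], **overrides) -> RunConfig:
    """Build a RunConfig from flat YAML-style key-value text (or a dict),
    filling defaults (omega=100, theta=(2.0, 1.5, 1.0), psi=50,
    method=spearman). Keyword overrides win over file values."""
    if isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ValueError("config must be flat key-value text")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    for req in ("expression", "tfs", "out"):
        if req not in data:
            raise ValueError(f"config is missing required key {req!r}")
    assoc = AssociationParams(
        method=data.get("method", "spearman"),
        omega=int(data.get("omega", 100)),
        min_samples=int(data.get("min_samples", 50)),
        direction=data.get("direction", "positive"),
    )
    triple = TripleLinkParams(
        theta1=float(data.get("theta1", 2.0)),
        theta2=float(data.get("theta2", 1.5)),
        theta3=float(data.get("theta3", 1.0)),
    )
    return RunConfig(
        expression=str(data["expression"]),
        tfs=str(data["tfs"]),
        out=str(data["out"]),
        dialect=data.get("dialect", "tsv"),
        missing=data.get("missing", "error"),
        assoc=assoc,
        triple=triple,
        workers=int(data.get("workers", 1)),
        log_level=str(data.get("log_level", "INFO")),
    )


def write_neighborhoods(neighborhoods, method: str, path) -> None:
    rows = []
    for nb in neighborhoods:
        for rank, (gene, score) in enumerate(zip(nb.members, nb.scores), start=1):
            rows.append(
                {"tf_id": nb.tf_id, "rank": rank, "gene_id": gene,
                 "score": float(score), "method": method}
            )
    write_table(rows, path, columns=("tf_id", "rank", "gene_id", "score", "method"))


def write_clusters(result: ClusteringResult, tsv_path, json_path=None) -> None:
    rows = []
    for cl in result.clusters:
        audit_by_tf = {a.tf_id: a for a in cl.audits}
        for join_rank, tf in enumerate(cl.members, start=1):
            if tf in audit_by_tf:
                witness = ";".join(
                    f"{m}:{v}" for m, v in audit_by_tf[tf].witness_links
                )
            else:  # seed member
                other = cl.seed[1] if tf == cl.seed[0] else cl.seed[0]
                witness = f"{other}:{cl.seed[2]}"
            rows.append(
                {
                    "cluster_id": cl.cluster_id,
                    "join_rank": join_rank,
                    "tf_id": tf,
                    "seed_flag": int(join_rank <= 2),
                    "witness_links": witness,
                }
            )
    write_table(
        rows, tsv_path,
        columns=("cluster_id", "join_rank", "tf_id", "seed_flag", "witness_links"),
    )
    if json_path is not None:
        with open(json_path, "w", newline="\n") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def export_graphml(sccm: SCCM, result: Optional[ClusteringResult], path) -> None:
    """SCCM as GraphML with n_c edge weights and, when a decomposition is
    given, cluster membership as a node attribute (0 = unclustered)."""
    g = nx.Graph()
    labels = result.labels() if result is not None else {}
    for tf in sccm.tf_ids:
        g.add_node(tf, cluster=int(labels.get(tf, 0)))
    for a, b, v in sorted(sccm.id_pairs()):
        g.add_edge(a, b, n_c=int(v))
    nx.write_graphml(g, path)


def run_pipeline(config: RunConfig) -> ClusteringResult:
    """Execute the full pipeline and write all artifacts into
    ``config.out``: neighborhoods.tsv, sccm_edges.tsv, clusters.tsv,
    clusters.json, sccm.graphml, run_log.txt."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    expr = stage("load-expression", load_expression, config.expression,
                 dialect=config.dialect, missing=config.missing)
    tfs = stage("load-tfs", load_tf_list, config.tfs, expr)
    log.info("loaded %d genes x %d samples, %d TFs", expr.n_genes,
             expr.n_samples, len(tfs))

    neighborhoods = stage(
        "coexpression", all_neighborhoods, expr, tfs, config.assoc,
        workers=config.workers,
    )
    write_neighborhoods(neighborhoods, config.assoc.method, out / "neighborhoods.tsv")

    sccm = stage("sccm", build_sccm, neighborhoods)
    export_sccm(sccm, out / "sccm_edges.tsv", format="edge-list-tsv")
    try:
        stats = connectivity_stats(sccm)
    except ValueError as exc:
        raise RuntimeError(
            f"[sccm] {exc} (the SCCM is empty: no TF pair shares any "
            "coexpressed gene; try a larger omega or more samples)"
        ) from exc

    result = stage("triple-link", decompose, sccm, config.triple)
    write_clusters(result, out / "clusters.tsv", out / "clusters.json")
    export_graphml(sccm, result, out / "sccm.graphml")

    with open(out / "run_log.txt", "w", newline="\n") as fh:
        fh.write("tfcluster run log\n")
        fh.write(f"expression\t{config.expression}\n")
        fh.write(f"tfs\t{config.tfs}\n")
        fh.write(f"genes\t{expr.n_genes}\n")
        fh.write(f"samples\t{expr.n_samples}\n")
        fh.write(f"tfs_used\t{len(neighborhoods)}\n")
        fh.write(f"method\t{config.assoc.method}\n")
        fh.write(f"omega\t{config.assoc.omega}\n")
        fh.write(f"direction\t{config.assoc.direction}\n")
        fh.write(f"theta\t{config.triple.theta1} {config.triple.theta2} "
                 f"{config.triple.theta3}\n")
        fh.write(f"mu\t{stats.mu:.6g}\n")
        fh.write(f"delta\t{stats.delta:.6g}\n")
        fh.write(f"n_nonzero\t{stats.n_nonzero}\n")
        for k, tau in enumerate(result.taus, start=1):
            fh.write(f"tau{k}\t{tau:.6g}\n")
        fh.write(f"n_clusters\t{len(result.clusters)}\n")
        for cl in result.clusters:
            fh.write(
                f"cluster\t{cl.cluster_id}\tsize={len(cl)}\t"
                f"seed={cl.seed[0]},{cl.seed[1]}\tseed_nc={cl.seed[2]}\n"
            )
        fh.write(f"n_unclustered\t{len(result.unclustered)}\n")
    log.info("extracted %d clusters, %d TFs unclustered",
             len(result.clusters), len(result.unclustered))
    return result
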