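"""End-to-end orchestration: build -> topology -> clusters -> motifs -> enrichment -> TFBS.

Each stage writes its TSV before the next starts, so partial outputs survive
a failing run; optional inputs (PPI table, gene sets, PWM/FASTA) simply skip
their stage.  The report records seed and full configuration, which is
sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import MirPathConfig, go_annotate, mirpath_analyze, read_gmt
from .mcode import MCODEParams, mcode_clusters
from .motifs import motif_census, motif_null
from .netmodel import (
    assemble_network,
    read_edge_table,
    read_node_table,
    read_ppi,
    summarize,
    write_graph,
)
from .tfbs import read_transfac_counts, scan, write_bed
from .topology import fit_power_law, hub_bottleneck, rank_hub_mirnas

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    edges: str | None = None
    nodes: str | None = None
    ppi: str | None = None
    gmt: str | None = None
    targets: str | None = None          # TSV: miRNA, gene, score
    go_gmt: str | None = None
    pwm: str | None = None
    fasta: str | None = None
    out_dir: str = "results"
    prune: bool = True
    quantile: float = 0.2
    mcode: MCODEParams = field(default_factory=MCODEParams)
    mirpath: MirPathConfig = field(default_factory=MirPathConfig)
    null_samples: int = 100
    null_rewires: int = 100
    css_cutoff: float = 0.75
    mss_cutoff: float = 0.85
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mcode = MCODEParams(**raw.pop("mcode", {}))
        mirpath = MirPathConfig(**raw.pop("mirpath", {}))
        return cls(mcode=mcode, mirpath=mirpath, **raw)


@dataclass
class AnalysisReport:
    summary: dict | None = None
    centrality: dict | None = None
    clusters: list | None = None
    motifs: dict | None = None
    enrichment: list | None = None
    go: list | None = None
    tfbs_hits: int | None = None
    provenance: dict = field(default_factory=dict)


def _stage(name: str, **info) -> None:
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


def run_all(config: PipelineConfig) -> AnalysisReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport()
    report.provenance = {
        "tool": "regnet",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
    }

    net = None
    clusters = []
    if config.edges and config.nodes:
        nodes = read_node_table(config.nodes)
        edges = read_edge_table(config.edges)
        net = assemble_network(nodes, edges, prune=config.prune)
        write_graph(net, out / "net.graphml", "graphml")
        s = summarize(net)
        report.summary = dataclasses.asdict(s)
        pd.DataFrame([report.summary]).to_json(out / "summary.json", orient="records", indent=2)
        _stage("build", nodes=s.n_nodes, edges=s.n_edges)

    ppi = None
    if config.ppi:
        ppi = read_ppi(config.ppi)
        rep = hub_bottleneck(ppi, quantile=config.quantile)
        rows = [
            {
                "id": v,
                "degree": rep.degree[v],
                "betweenness": rep.betweenness[v],
                "is_hub": v in rep.hub_set,
                "is_bottleneck": v in rep.bottleneck_set,
                "is_hub_bottleneck": v in rep.hub_bottleneck_set,
            }
            for v in sorted(rep.degree)
        ]
        pd.DataFrame(rows).to_csv(out / "centrality.tsv", sep="\t", index=False)
        fit = fit_power_law(rep.degree) if len(set(rep.degree.values()) - {0}) >= 2 else None
        report.centrality = {
            "n_hub": len(rep.hub_set),
            "n_bottleneck": len(rep.bottleneck_set),
            "n_hub_bottleneck": len(rep.hub_bottleneck_set),
            "power_law_slope": fit.slope if fit else None,
            "power_law_r2": fit.r_squared if fit else None,
        }
        _stage("topology", **report.centrality)

        clusters = mcode_clusters(ppi, config.mcode)
        pd.DataFrame(
            [
                {
                    "rank": c.rank, "n_nodes": c.n_nodes, "n_edges": c.n_edges,
                    "score": round(c.score, 3), "seed": c.seed,
                    "seed_weight": round(c.seed_weight, 3),
                    "members": ",".join(sorted(c.members)),
                }
                for c in clusters
            ]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        report.clusters = [
            {"rank": c.rank, "n_nodes": c.n_nodes, "n_edges": c.n_edges, "score": c.score}
            for c in clusters
        ]
        _stage("mcode", n_clusters=len(clusters))

    if net is not None:
        census = motif_census(net)
        if config.null_samples > 0:
            census = motif_null(
                net, census, n_rewires=config.null_rewires,
                n_samples=config.null_samples, seed=config.seed,
            )
        pd.DataFrame(
            [
                {
                    "motif_type": m.motif_type,
                    "members": ",".join(m.members),
                    "signs": ",".join(m.signs),
                    "classification": m.classification,
                }
                for m in census.instances
            ]
        ).to_csv(out / "motifs.tsv", sep="\t", index=False)
        report.motifs = {
            "counts": census.counts,
            "z_score": census.z_score,
            "hub_mirnas": rank_hub_mirnas(net, clusters, k=10),
        }
        _stage("motifs", **census.counts)

    if config.targets and config.gmt:
        pathways = read_gmt(config.gmt)
        tdf = pd.read_csv(config.targets, sep="\t", comment="#")
        targets = {
            m: dict(zip(sub.iloc[:, 1], sub.iloc[:, 2].astype(float)))
            for m, sub in tdf.groupby(tdf.columns[0])
        }
        results = mirpath_analyze(targets, pathways, config.mirpath)
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out / "enrich.tsv", sep="\t", index=False
        )
        report.enrichment = [
            {"term": r.term, "p_raw": r.p_raw, "p_adjusted": r.p_adjusted} for r in results[:20]
        ]
        _stage("enrichment", n_pathways=len(results))

    if config.go_gmt and clusters:
        goterms = read_gmt(config.go_gmt)
        rows = []
        for c in clusters:
            for r in go_annotate(c.members, goterms):
                rows.append(
                    {"cluster": c.rank, "term": r.term, "corr_p": r.p_adjusted,
                     "x": r.k, "description": r.name}
                )
        pd.DataFrame(rows).to_csv(out / "go.tsv", sep="\t", index=False)
        report.go = rows[:20]
        _stage("go", n_rows=len(rows))

    if config.pwm and config.fasta:
        pwm = read_transfac_counts(config.pwm)
        from Bio import SeqIO

        hits = scan(pwm, SeqIO.parse(config.fasta, "fasta"),
                    css_cutoff=config.css_cutoff, mss_cutoff=config.mss_cutoff)
        write_bed(hits, out / "hits.bed", pwm.length)
        report.tfbs_hits = len(hits)
        _stage("tfbs", n_hits=len(hits))

    _write_report_md(report, out / "report.md")
    return report


def _write_report_md(report: AnalysisReport, path: Path) -> None:
    lines = ["# regnet analysis report", ""]
    if report.summary:
        lines += [
            "## Network",
            f"- nodes: {report.summary['n_nodes']}, edges: {report.summary['n_edges']}",
            f"- by class: {report.summary['counts_by_class']}",
            "",
        ]
    if report.centrality:
        lines += ["## PPI topology", f"- {report.centrality}", ""]
    if report.clusters is not None:
        lines += ["## MCODE clusters"] + [
            f"- rank {c['rank']}: {c['n_nodes']} nodes / {c['n_edges']} edges, score {c['score']:.3f}"
            for c in report.clusters
        ] + [""]
    if report.motifs:
        lines += ["## Motifs", f"- counts: {report.motifs['counts']}",
                  f"- z: {report.motifs['z_score']}",
                  f"- hub miRNAs: {', '.join(report.motifs['hub_mirnas'])}", ""]
    if report.enrichment is not None:
        lines += ["## Enrichment (top)"] + [
            f"- {r['term']}: p={r['p_raw']:.3g} q={r['p_adjusted']:.3g}"
            for r in report.enrichment[:10]
        ] + [""]
    if report.tfbs_hits is not None:
        lines += ["## TFBS scan", f"- hits: {report.tfbs_hits}", ""]
    lines += ["## Provenance", f"- seed: {report.provenance.get('seed')}",
              f"- version: {report.provenance.get('version')}"]
    path.write_text("\n".join(lines))
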