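"""End-to-end orchestration: genomes in, contextual network and report out.

Stages: parse/simulate -> find queries -> extract windows -> cluster
neighbor proteins -> annotate (operons, divergent pairs) -> cull
near-identical queries and dereplicate -> contextual network ->
co-occurrence -> report. Every output is deterministic given the config
and master seed; the run log records per-stage counts and the config hash.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import Partition, assign_labels, cluster_sequences
from .genome import GenomeTable
from .io import parse_ptt, read_fasta
from .neighborhood import (AnnotatedNeighborhood, annotate_neighborhood,
                           extract_neighborhood, find_queries)
from .network import (ContextGraph, CooccurrenceStat, build_context_graph,
                      cooccurrence_fraction, dereplicate_neighborhoods,
                      export_graph)
from .simulate import PangenomeConfig, generate_pangenome

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


def _plain(obj):
    """Dataclass tree -> plain JSON/YAML-serializable structure."""
    return json.loads(json.dumps(dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else obj))


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults are the package's documented ones."""

    seed: int = 0
    genomes_dir: str | None = None
    simulate: PangenomeConfig | None = None
    query_seeds: dict[str, str] | None = None   # family -> seed FASTA path
    targets: dict[str, list[str]] | None = None  # family -> target labels
    identity: float = 30.0
    coverage: float = 0.6
    cull_identity: float = 95.0
    cull_coverage: float = 0.9
    k: int = 5
    max_gap: int = 150
    bidir_window: int = 300
    consensus_threshold: float = 0.85
    screen_kmer: int | None = 5

    def validate(self) -> None:
        if (self.genomes_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of genomes_dir / simulate required")
        for name, val, lo, hi in [("identity", self.identity, 0, 100),
                                  ("coverage", self.coverage, 0, 1),
                                  ("cull_identity", self.cull_identity, 0, 100),
                                  ("cull_coverage", self.cull_coverage, 0, 1),
                                  ("consensus_threshold", self.consensus_threshold, 0, 1)]:
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def digest(self) -> str:
        payload = yaml.safe_dump(_plain(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FamilyResult:
    family: str
    n_queries: int
    n_dereplicated: int
    cooccurrence: CooccurrenceStat
    genome_fraction: float
    operon_fraction: float


@dataclass
class RunReport:
    config_digest: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    families: dict[str, FamilyResult] = field(default_factory=dict)
    graph: ContextGraph | None = None
    annotated: dict[str, list[AnnotatedNeighborhood]] = field(default_factory=dict)
    partition: Partition | None = None
    log_lines: list[str] = field(default_factory=list)


def load_genome_dir(path: str | Path) -> list[GenomeTable]:
    """Load ``<genome>.ptt`` + ``<genome>.faa`` pairs from a directory."""
    path = Path(path)
    tables = []
    for ptt in sorted(path.glob("*.ptt")):
        genome_id = ptt.stem
        table = parse_ptt(ptt.read_text(), genome_id)
        faa = ptt.with_suffix(".faa")
        if faa.exists():
            proteins = dict(read_fasta(faa.read_text()))
            for g in table.genes:
                g.protein = proteins.get(g.pid)
        tables.append(table)
    if not tables:
        raise FileNotFoundError(f"no .ptt files under {path}")
    return tables


def _seeds_from_config(config: PipelineConfig) -> dict[str, list[tuple[str, str]]]:
    if config.query_seeds:
        return {fam: read_fasta(Path(p).read_text())
                for fam, p in config.query_seeds.items()}
    if config.simulate is not None:
        return {f.family_id: [(f.family_id, f.ancestral_protein)]
                for f in config.simulate.families if f.role == "query"}
    raise ValueError("no query seeds configured")


def _targets_from_config(config: PipelineConfig,
                         seeds: dict) -> dict[str, list[str]]:
    if config.targets:
        return config.targets
    if config.simulate is None:
        raise ValueError("no co-occurrence targets configured")
    roles = {f.family_id: f.role for f in config.simulate.families}
    out: dict[str, list[str]] = {}
    for fam in seeds:
        partners: set[str] = set()
        for t in config.simulate.templates:
            fams = [fid for fid, _ in t.genes]
            if t.divergent_partner:
                fams.append(t.divergent_partner)
            if fam in fams:
                partners.update(f for f in fams
                                if f != fam and roles.get(f) == "context")
        out[fam] = sorted(partners)
    return out


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> RunReport:
    """Execute the full contextual analysis; optionally write the output set.

    Files written (all deterministic given config + seed): clusters.tsv,
    neighborhoods.tsv, edges.tsv, cooccurrence.tsv, graph.graphml,
    graph.dot, report.json, manifest.yaml, run.log. On a stage error,
    nothing is written.
    """
    config.validate()
    report = RunReport(config_digest=config.digest())

    def note(stage: str, msg: str) -> None:
        line = f"{stage}: {msg}"
        report.log_lines.append(line)
        log.info(line)

    stage = "parse"
    try:
        if config.simulate is not None:
            tables, _truth = generate_pangenome(config.simulate, config.seed)
        else:
            tables = load_genome_dir(config.genomes_dir)
        n_genes = sum(len(t) for t in tables)
        report.stage_counts["genomes"] = len(tables)
        report.stage_counts["genes"] = n_genes
        note(stage, f"{len(tables)} genomes, {n_genes} genes")
        table_of = {t.genome_id: t for t in tables}

        stage = "find_queries"
        sim_cache: dict = {}  # shared across stages; similarities are threshold-free
        seeds = _seeds_from_config(config)
        targets = _targets_from_config(config, seeds)
        queries = find_queries(tables, seeds, config.identity, config.coverage,
                               screen_kmer=config.screen_kmer, cache=sim_cache)
        report.stage_counts["queries"] = sum(len(v) for v in queries.values())
        for fam, genes in queries.items():
            note(stage, f"{fam}: {len(genes)} query genes")

        stage = "extract"
        windows = {
            fam: [extract_neighborhood(table_of[g.genome_id], g.index, config.k)
                  for g in genes]
            for fam, genes in queries.items()}
        report.stage_counts["neighborhoods"] = sum(len(v) for v in windows.values())

        stage = "cluster"
        window_genes = {}
        for nbhds in windows.values():
            for nb in nbhds:
                for g in nb.genes:
                    if g.protein is None:
                        raise PipelineError(
                            f"stage cluster: gene {g.pid} has no protein sequence")
                    window_genes[g.pid] = g
        if not window_genes:
            raise PipelineError("stage cluster: no neighborhood proteins "
                                "(no queries found)")
        items = sorted((pid, g.protein) for pid, g in window_genes.items())
        partition = cluster_sequences(items, config.identity, config.coverage,
                                      screen_kmer=config.screen_kmer,
                                      cache=sim_cache)
        assign_labels(partition, {pid: g.product for pid, g in window_genes.items()})
        report.partition = partition
        report.stage_counts["neighbor_proteins"] = len(items)
        report.stage_counts["clusters"] = len(partition.clusters)
        note(stage, f"{len(items)} proteins -> {len(partition.clusters)} clusters")

        stage = "annotate"
        annotated = {
            fam: [annotate_neighborhood(nb, partition, max_gap=config.max_gap,
                                        bidir_window=config.bidir_window)
                  for nb in nbhds]
            for fam, nbhds in windows.items()}

        stage = "dereplicate"
        derep: dict[str, list[AnnotatedNeighborhood]] = {}
        for fam, anns in annotated.items():
            if not anns:
                derep[fam] = []
                continue
            qitems = sorted((a.neighborhood.query_pid, a.neighborhood.query.protein)
                            for a in anns)
            culling = cluster_sequences(qitems, config.cull_identity,
                                        config.cull_coverage,
                                        screen_kmer=config.screen_kmer,
                                        cache=sim_cache)
            derep[fam] = dereplicate_neighborhoods(anns, culling)
            note(stage, f"{fam}: {len(anns)} -> {len(derep[fam])} neighborhoods")
        report.annotated = derep
        report.stage_counts["dereplicated"] = sum(len(v) for v in derep.values())

        stage = "network"
        all_anns = [a for fam in sorted(derep) for a in derep[fam]]
        graph = build_context_graph(all_anns)
        report.graph = graph
        note(stage, f"{len(graph.nodes)} nodes, "
                    f"{len(graph.adjacency)} adjacency edges, "
                    f"{len(graph.divergent)} divergent edges")

        stage = "cooccurrence"
        for fam, anns in derep.items():
            if not anns:
                continue
            stat = cooccurrence_fraction(anns, targets.get(fam, []),
                                         query_family=fam)
            genomes = {a.neighborhood.genome_id for a in anns}
            hit_genomes = {
                a.neighborhood.genome_id for a in anns
                if any(a.labels[g.pid] in set(targets.get(fam, []))
                       for g in a.neighborhood.genes
                       if g.pid != a.neighborhood.query_pid)}
            operon_hits = sum(
                1 for a in anns
                if any(a.labels[g.pid] in set(targets.get(fam, []))
                       for g in a.operon.genes
                       if g.pid != a.neighborhood.query_pid))
            report.families[fam] = FamilyResult(
                fam, len(annotated[fam]), len(anns), stat,
                genome_fraction=len(hit_genomes) / len(genomes),
                operon_fraction=operon_hits / len(anns))
            note(stage, f"{fam}: {stat.n_with_target}/{stat.n_neighborhoods} "
                        f"= {stat.fraction:.3f} with {stat.target_families}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    if out_dir is not None:
        _write_outputs(config, report, targets, Path(out_dir))
    return report


def _neighborhood_rows(report: RunReport) -> pd.DataFrame:
    rows = []
    for fam in sorted(report.annotated):
        for ann in report.annotated[fam]:
            nb = ann.neighborhood
            operon_pids = set(ann.operon.pids)
            div_pids = {p.upstream.pid for p in ann.divergent} | {
                p.downstream.pid for p in ann.divergent}
            prev = None
            for off, g in zip(nb.offsets, nb.genes):
                rows.append({
                    "family": fam, "genome": nb.genome_id, "query_pid": nb.query_pid,
                    "offset": off, "pid": g.pid, "strand": g.strand,
                    "gap_to_previous": nb.gap_between(prev, g) if prev else "",
                    "label": ann.labels[g.pid],
                    "in_operon": int(g.pid in operon_pids),
                    "divergent": int(g.pid in div_pids),
                })
                prev = g
    return pd.DataFrame(rows)


def _write_outputs(config: PipelineConfig, report: RunReport,
                   targets: dict[str, list[str]], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    part = report.partition
    clusters = pd.DataFrame([
        {"cluster_id": c.cluster_id, "representative": c.representative,
         "size": len(c.members), "label": c.label, "members": ",".join(c.members)}
        for c in part.clusters])
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    _neighborhood_rows(report).to_csv(out / "neighborhoods.tsv", sep="\t", index=False)
    (out / "edges.tsv").write_text(export_graph(report.graph, "tsv"))
    (out / "graph.graphml").write_text(export_graph(report.graph, "graphml"))
    (out / "graph.dot").write_text(export_graph(report.graph, "dot"))
    cooc = pd.DataFrame([
        {"query_family": fr.family,
         "target_set": ",".join(fr.cooccurrence.target_families),
         "n_neighborhoods": fr.cooccurrence.n_neighborhoods,
         "k_neighborhoods": fr.cooccurrence.n_with_target,
         "fraction_neighborhoods": round(fr.cooccurrence.fraction, 6),
         "fraction_genomes": round(fr.genome_fraction, 6),
         "fraction_operons": round(fr.operon_fraction, 6)}
        for fr in report.families.values()])
    cooc.to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
    summary = {
        "version": __version__,
        "config_digest": report.config_digest,
        "stage_counts": report.stage_counts,
        "families": {
            fam: {"n_queries": fr.n_queries,
                  "n_dereplicated": fr.n_dereplicated,
                  "fraction": fr.cooccurrence.fraction,
                  "targets": list(fr.cooccurrence.target_families)}
            for fam, fr in report.families.items()},
    }
    (out / "report.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    manifest = {"version": __version__, "config": _plain(config),
                "config_digest": report.config_digest, "targets": targets}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    (out / "run.log").write_text("\n".join(report.log_lines) + "\n")
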