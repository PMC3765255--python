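"""Contextual gene-association networks and co-occurrence statistics.

Nodes are gene-family labels. A directed edge u->v records that a u-family
gene sits immediately 5' of a v-family gene inside one operon; a separate
undirected "divergent" edge records a head-to-head bidirectional-promoter
arrangement (the edge type drawn with circular ends in contextual-network
figures). Edge counts are numbers of distinct (genome, query) witnesses, so
multi-replicon strains cannot double-count.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx

from .cluster import Partition
from .neighborhood import AnnotatedNeighborhood


@dataclass
class ContextGraph:
    """Gene-family association graph with witness bookkeeping."""

    adjacency: dict[tuple[str, str], set[tuple[str, str]]] = field(default_factory=dict)
    divergent: dict[tuple[str, str], set[tuple[str, str]]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        labels = set()
        for u, v in list(self.adjacency) + list(self.divergent):
            labels.update((u, v))
        return sorted(labels)

    def adjacency_count(self, u: str, v: str) -> int:
        return len(self.adjacency.get((u, v), ()))

    def divergent_count(self, u: str, v: str) -> int:
        return len(self.divergent.get(tuple(sorted((u, v))), ()))

    def total_adjacency_support(self) -> int:
        return sum(len(w) for w in self.adjacency.values())


@dataclass
class CooccurrenceStat:
    """Fraction of a query family's neighborhoods containing a target family."""

    query_family: str
    target_families: tuple[str, ...]
    n_neighborhoods: int
    n_with_target: int

    @property
    def fraction(self) -> float:
        return self.n_with_target / self.n_neighborhoods

    @property
    def exact(self) -> Fraction:
        return Fraction(self.n_with_target, self.n_neighborhoods)


def build_context_graph(annotated: Iterable[AnnotatedNeighborhood]) -> ContextGraph:
    """Aggregate annotated neighborhoods into a :class:`ContextGraph`.

    Each consecutive label pair of each operon signature adds support to a
    directed edge; each divergent pair adds support to an undirected edge.
    Construction is permutation-invariant because edges carry witness sets.
    """
    graph = ContextGraph()
    for ann in annotated:
        witness = (ann.neighborhood.genome_id, ann.neighborhood.query_pid)
        sig = ann.signature
        for (u, _), (v, _) in zip(sig, sig[1:]):
            graph.adjacency.setdefault((u, v), set()).add(witness)
        for pair in ann.divergent:
            lu = ann.labels[pair.upstream.pid]
            lv = ann.labels[pair.downstream.pid]
            key = tuple(sorted((lu, lv)))
            graph.divergent.setdefault(key, set()).add(witness)
    return graph


def cooccurrence_fraction(annotated: Sequence[AnnotatedNeighborhood],
                          target_labels: Iterable[str], *,
                          query_family: str = "query") -> CooccurrenceStat:
    """Fraction of neighborhoods with >=1 non-query gene in ``target_labels``.

    The input should already be dereplicated; an empty input is an error
    (the fraction is undefined).
    """
    targets = set(target_labels)
    if not annotated:
        raise ValueError("cannot compute a co-occurrence fraction of zero neighborhoods")
    hits = 0
    for ann in annotated:
        qpid = ann.neighborhood.query_pid
        if any(ann.labels[g.pid] in targets
               for g in ann.neighborhood.genes if g.pid != qpid):
            hits += 1
    return CooccurrenceStat(query_family, tuple(sorted(targets)),
                            len(annotated), hits)


def dereplicate_neighborhoods(annotated: Sequence[AnnotatedNeighborhood],
                              culling: Partition) -> list[AnnotatedNeighborhood]:
    """One neighborhood per near-identity cluster of query proteins.

    ``culling`` is a partition of the query proteins at the culling
    thresholds; the retained neighborhood is the one whose query is the
    cluster representative (longest protein, ties by pid).
    """
    by_pid = {ann.neighborhood.query_pid: ann for ann in annotated}
    kept = []
    for c in culling.clusters:
        if c.representative in by_pid:
            kept.append(by_pid[c.representative])
    return kept


def to_networkx(graph: ContextGraph) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for label in graph.nodes:
        g.add_node(label)
    for (u, v), wit in sorted(graph.adjacency.items()):
        g.add_edge(u, v, kind="adjacency", count=len(wit))
    for (u, v), wit in sorted(graph.divergent.items()):
        g.add_edge(u, v, kind="divergent", count=len(wit))
    return g


def export_graph(graph: ContextGraph, format: str = "graphml") -> str:
    """Serialize as GraphML, DOT (divergent edges get circular ends) or TSV."""
    if format == "graphml":
        buf = _io.BytesIO()
        nx.write_graphml(to_networkx(graph), buf)
        return buf.getvalue().decode()
    if format == "dot":
        lines = ["digraph context {"]
        for label in graph.nodes:
            lines.append(f'    "{label}";')
        for (u, v), wit in sorted(graph.adjacency.items()):
            lines.append(f'    "{u}" -> "{v}" [label={len(wit)}];')
        for (u, v), wit in sorted(graph.divergent.items()):
            lines.append(
                f'    "{u}" -> "{v}" [label={len(wit)}, dir=both, '
                "arrowhead=odot, arrowtail=odot];")
        lines.append("}")
        return "\n".join(lines) + "\n"
    if format == "tsv":
        lines = ["u\tv\tkind\tcount"]
        for (u, v), wit in sorted(graph.adjacency.items()):
            lines.append(f"{u}\t{v}\tadjacency\t{len(wit)}")
        for (u, v), wit in sorted(graph.divergent.items()):
            lines.append(f"{u}\t{v}\tdivergent\t{len(wit)}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")
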