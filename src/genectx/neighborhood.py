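"""Gene-neighborhood extraction and operon refinement.

The unit of analysis is the window of +/-k genes (default k=5) around each
query gene. Within a window, the operon containing the query is the maximal
run of consecutive, co-directional genes whose successive intergenic gaps do
not exceed a threshold (default 150 bp) -- distance standing in for "shares
a promoter". Head-to-head gene pairs on opposite strands across a short
intergenic region are reported separately as candidate bidirectional-promoter
(divergent) arrangements.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cluster import Partition, cluster_sequences
from .genome import GeneRecord, GenomeTable


@dataclass
class Neighborhood:
    """The ordered +/-k gene window around one query gene.

    ``genes`` and ``offsets`` are parallel; the query sits at offset 0.
    Windows are clipped at the ends of linear replicons and wrap (without
    duplication) on circular ones.
    """

    query_pid: str
    genome_id: str
    replicon_id: str
    k: int
    genes: list[GeneRecord]
    offsets: list[int]
    replicon_length: int = 0
    circular: bool = False

    @property
    def query(self) -> GeneRecord:
        return self.genes[self.offsets.index(0)]

    def gap_between(self, a: GeneRecord, b: GeneRecord) -> int:
        """Intergenic gap between window-consecutive a and b, wrap-aware."""
        if self.circular and b.start <= a.start:
            return b.start + self.replicon_length - a.end - 1
        return b.start - a.end - 1


@dataclass
class OperonBlock:
    """Co-directional, gap-bounded run of consecutive genes with the query."""

    genes: list[GeneRecord]
    query_pid: str
    max_internal_gap: int

    @property
    def pids(self) -> tuple[str, ...]:
        return tuple(g.pid for g in self.genes)


@dataclass
class DivergentPair:
    """Two head-to-head genes (<- then ->) across a short intergenic region."""

    upstream: GeneRecord   # the - strand gene, first in coordinates
    downstream: GeneRecord  # the + strand gene
    separation: int


@dataclass
class AnnotatedNeighborhood:
    """A neighborhood with family labels, its operon and divergent pairs.

    ``signature`` is the operon read 5'->3' along the query's strand as
    (label, strand-relative-to-query) tuples, so instances of the same
    operon on opposite genomic strands compare equal.
    """

    neighborhood: Neighborhood
    labels: dict[str, str]
    operon: OperonBlock
    divergent: list[DivergentPair]
    signature: tuple[tuple[str, str], ...] = field(default_factory=tuple)


def find_queries(tables: Sequence[GenomeTable],
                 seed_sequences: Mapping[str, Sequence[tuple[str, str]]],
                 identity_threshold: float = 30.0,
                 coverage_threshold: float = 0.6, *,
                 screen_kmer: int | None = None,
                 cache: dict | None = None,
                 ) -> dict[str, list[GeneRecord]]:
    """Find genes clustering with the seeds of each query family.

    ``seed_sequences`` maps family name -> seed FASTA records. Seeds and all
    genome proteins are clustered together (single linkage at the given
    thresholds); a gene is a query for a family iff it shares a cluster with
    at least one of that family's seeds. Returns family -> query genes
    (deterministic order); families with no hits map to empty lists.
    """
    gene_by_pid: dict[str, GeneRecord] = {}
    items: list[tuple[str, str]] = []
    for table in tables:
        for g in table.genes:
            if g.protein:
                gene_by_pid[g.pid] = g
                items.append((g.pid, g.protein))
    seed_pids: dict[str, list[str]] = {}
    for fam, recs in seed_sequences.items():
        seed_pids[fam] = []
        for sid, seq in recs:
            spid = f"seed::{fam}::{sid}"
            seed_pids[fam].append(spid)
            items.append((spid, seq))
    out: dict[str, list[GeneRecord]] = {fam: [] for fam in seed_sequences}
    if not gene_by_pid:
        return out
    part = cluster_sequences(items, identity_threshold, coverage_threshold,
                             screen_kmer=screen_kmer, cache=cache)
    for fam, spids in seed_pids.items():
        hit_clusters = {part.assignments[s] for s in spids}
        hits = [pid for pid, cid in part.assignments.items()
                if cid in hit_clusters and pid in gene_by_pid]
        out[fam] = [gene_by_pid[pid] for pid in sorted(hits)]
    return out


def extract_neighborhood(table: GenomeTable, query_index: int,
                         k: int = 5) -> Neighborhood:
    """Genes at ordinal offsets -k..+k around the query.

    Clipped at the ends of a linear replicon; wraps on a circular one,
    never returning the same gene twice.
    """
    n = len(table.genes)
    if not 0 <= query_index < n:
        raise IndexError(f"query_index {query_index} out of range (n={n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    genes: list[GeneRecord] = []
    offsets: list[int] = []
    seen: set[int] = set()
    for off in range(-k, k + 1):
        idx = query_index + off
        if table.circular:
            idx %= n
        elif not 0 <= idx < n:
            continue
        if idx in seen:
            continue
        seen.add(idx)
        genes.append(table.genes[idx])
        offsets.append(off)
    q = table.genes[query_index]
    return Neighborhood(q.pid, q.genome_id, table.replicon_id, k, genes,
                        offsets, table.replicon_length, table.circular)


def intergenic_gap(a: GeneRecord, b: GeneRecord) -> int:
    """``start(b) - end(a) - 1`` for a preceding b; negative on overlap."""
    if a.replicon_id != b.replicon_id:
        raise ValueError(
            f"{a.pid} and {b.pid} are on different replicons "
            f"({a.replicon_id!r} vs {b.replicon_id!r})")
    return b.start - a.end - 1


def infer_operon(nbhd: Neighborhood, max_gap: int = 150) -> OperonBlock:
    """Greedy co-directional extension of the query's transcription unit.

    Starting from the query, neighbors are added in both directions while
    they share the query's strand and the consecutive intergenic gap is at
    most ``max_gap``. Overlapping co-directional genes (negative gap) are
    always joined -- overlap implies translational coupling. The block
    always contains at least the query.
    """
    pos = nbhd.offsets.index(0)
    strand = nbhd.genes[pos].strand
    lo = pos
    while lo > 0 and nbhd.genes[lo - 1].strand == strand:
        gap = max(nbhd.gap_between(nbhd.genes[lo - 1], nbhd.genes[lo]), 0)
        if gap > max_gap:
            break
        lo -= 1
    hi = pos
    while hi < len(nbhd.genes) - 1 and nbhd.genes[hi + 1].strand == strand:
        gap = max(nbhd.gap_between(nbhd.genes[hi], nbhd.genes[hi + 1]), 0)
        if gap > max_gap:
            break
        hi += 1
    members = nbhd.genes[lo:hi + 1]
    gaps = [nbhd.gap_between(a, b) for a, b in zip(members, members[1:])]
    return OperonBlock(members, nbhd.query_pid,
                       max((max(g, 0) for g in gaps), default=0))


def detect_divergent_pairs(nbhd: Neighborhood,
                           bidir_window: int = 300) -> list[DivergentPair]:
    """Consecutive head-to-head (- then +) pairs within the gap window.

    Convergent (-> <-) and co-directional pairs are never reported.
    """
    out = []
    for a, b in zip(nbhd.genes, nbhd.genes[1:]):
        if a.strand == "-" and b.strand == "+":
            gap = nbhd.gap_between(a, b)
            if gap <= bidir_window:
                out.append(DivergentPair(a, b, gap))
    return out


def annotate_neighborhood(nbhd: Neighborhood, partition: Partition, *,
                          max_gap: int = 150,
                          bidir_window: int = 300) -> AnnotatedNeighborhood:
    """Tag every window gene with its cluster label and build the signature.

    Requires every pid of the window to be present (and labelled) in the
    partition; a missing pid is an error naming it.
    """
    labels: dict[str, str] = {}
    for g in nbhd.genes:
        if g.pid not in partition.assignments:
            raise KeyError(f"pid {g.pid!r} missing from partition")
        labels[g.pid] = partition.cluster_of(g.pid).label or ""
    operon = infer_operon(nbhd, max_gap)
    divergent = detect_divergent_pairs(nbhd, bidir_window)
    qstrand = nbhd.query.strand
    members = operon.genes if qstrand == "+" else list(reversed(operon.genes))
    signature = tuple(
        (labels[g.pid], "+" if g.strand == qstrand else "-") for g in members)
    return AnnotatedNeighborhood(nbhd, labels, operon, divergent, signature)
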