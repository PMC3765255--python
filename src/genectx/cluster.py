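"""Single-linkage protein-family clustering with identity/coverage thresholds.

Two sequences are neighbors when the optimal local alignment reaches the
identity threshold I (percent) and the coverage threshold L on *both*
sequences; families are the connected components of the neighbor graph
(single linkage, so chains of pairwise neighbors merge). Near-identical
sequences are culled with the same machinery at stricter thresholds.

By default every pair is aligned exactly. For large inputs an optional
shared-k-mer candidate screen restricts the exact DP to pairs sharing at
least one length-k exact word, the same candidate-generation idea used by
BLAST-based clustering tools; the screen only ever prunes pairs, never adds
them, and is off unless requested.
"""
from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import AlignParams, DEFAULT_PARAMS, PairSimilarity, encode, \
    _similarity_from_codes

#: Products ignored when voting for a cluster label.
DEFAULT_STOPWORDS = frozenset({
    "hypothetical", "hypothetical protein", "uncharacterized protein",
    "putative protein", "unknown",
})


def neighbor_test(sim: PairSimilarity, identity_threshold: float = 30.0,
                  coverage_threshold: float = 0.6) -> bool:
    """True iff identity >= I and coverage >= L on both sequences (inclusive)."""
    return (sim.percent_identity >= identity_threshold
            and min(sim.coverage_a, sim.coverage_b) >= coverage_threshold)


@dataclass
class Cluster:
    cluster_id: int
    representative: str
    members: list[str]
    label: str | None = None


@dataclass
class Partition:
    """A disjoint, covering clustering of protein ids.

    ``assignments`` maps every input pid to its cluster_id; ``clusters``
    lists clusters ordered by (size desc, representative pid), which is how
    cluster_ids are assigned.
    """

    assignments: dict[str, int] = field(default_factory=dict)
    clusters: list[Cluster] = field(default_factory=list)

    def cluster_of(self, pid: str) -> Cluster:
        return self.clusters[self.assignments[pid]]

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(c.members) for c in self.clusters}

    def validate(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if c.representative not in c.members:
                raise ValueError(f"cluster {c.cluster_id}: representative not a member")
            overlap = seen & set(c.members)
            if overlap:
                raise ValueError(f"clusters overlap on {sorted(overlap)[:3]}")
            seen |= set(c.members)
        if seen != set(self.assignments):
            raise ValueError("clusters do not cover the assigned pids")


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _as_items(seqs) -> list[tuple[str, str]]:
    if isinstance(seqs, Mapping):
        return list(seqs.items())
    return list(seqs)


def candidate_pairs(items: Sequence[tuple[str, str]], k: int) -> set[tuple[int, int]]:
    """Index pairs of sequences sharing at least one exact k-mer."""
    index: dict[str, list[int]] = defaultdict(list)
    for i, (_, seq) in enumerate(items):
        for w in {seq[p:p + k] for p in range(len(seq) - k + 1)}:
            index[w].append(i)
    pairs: set[tuple[int, int]] = set()
    for hits in index.values():
        if len(hits) > 1:
            pairs.update(itertools.combinations(hits, 2))
    return pairs


def pairwise_similarities(seqs, params: AlignParams | None = None, *,
                          screen_kmer: int | None = None,
                          cache: dict | None = None) -> list[PairSimilarity]:
    """Exact local-alignment similarities for all (or screened) pairs.

    ``cache`` (pid_a, pid_b) -> PairSimilarity lets successive clustering
    passes over overlapping sequence sets skip already-aligned pairs;
    similarities do not depend on thresholds, so reuse is exact.
    """
    params = params or DEFAULT_PARAMS
    items = _as_items(seqs)
    codes = [encode(s) for _, s in items]
    if screen_kmer is None:
        pairs: Iterable[tuple[int, int]] = itertools.combinations(range(len(items)), 2)
    else:
        pairs = sorted(candidate_pairs(items, screen_kmer))
    sims = []
    for i, j in pairs:
        key = (items[i][0], items[j][0])
        if cache is not None:
            hit = cache.get(key)
            if hit is not None:
                sims.append(hit)
                continue
        sim = _similarity_from_codes(codes[i], codes[j], params, key[0], key[1])
        if cache is not None:
            cache[key] = sim
        sims.append(sim)
    return sims


def cluster_sequences(seqs, identity_threshold: float = 30.0,
                      coverage_threshold: float = 0.6, *,
                      params: AlignParams | None = None,
                      screen_kmer: int | None = None,
                      cache: dict | None = None,
                      sims: Iterable[PairSimilarity] | None = None) -> Partition:
    """Single-linkage clustering of ``{pid: seq}`` (or ``[(pid, seq), ...]``).

    Clusters are the connected components of the neighbor-test-positive pair
    graph. The representative of a cluster is its longest member (ties to
    the lexicographically smallest pid); cluster_ids are assigned in
    (size desc, representative pid) order.
    """
    items = _as_items(seqs)
    if not items:
        raise ValueError("no sequences to cluster")
    lengths = {pid: len(s) for pid, s in items}
    if sims is None:
        sims = pairwise_similarities(items, params, screen_kmer=screen_kmer,
                                     cache=cache)
    uf = _UnionFind(pid for pid, _ in items)
    for sim in sims:
        if neighbor_test(sim, identity_threshold, coverage_threshold):
            uf.union(sim.pid_a, sim.pid_b)
    groups: dict[str, list[str]] = defaultdict(list)
    for pid, _ in items:
        groups[uf.find(pid)].append(pid)

    clusters = []
    for members in groups.values():
        rep = min(members, key=lambda p: (-lengths[p], p))
        clusters.append(Cluster(0, rep, sorted(members)))
    clusters.sort(key=lambda c: (-len(c.members), c.representative))
    part = Partition()
    for cid, c in enumerate(clusters):
        c.cluster_id = cid
        for pid in c.members:
            part.assignments[pid] = cid
    part.clusters = clusters
    return part


def cull_redundant(seqs, identity_threshold: float = 95.0,
                   coverage_threshold: float = 0.9, *,
                   params: AlignParams | None = None,
                   screen_kmer: int | None = None) -> list[tuple[str, str]]:
    """Keep one representative (longest; ties by pid) per near-identity cluster.

    Output is ordered by cluster_id, which is deterministic.
    """
    items = _as_items(seqs)
    seq_of = dict(items)
    part = cluster_sequences(items, identity_threshold, coverage_threshold,
                             params=params, screen_kmer=screen_kmer)
    return [(c.representative, seq_of[c.representative]) for c in part.clusters]


def assign_labels(partition: Partition, gene_products: Mapping[str, str], *,
                  stopwords: frozenset[str] = DEFAULT_STOPWORDS) -> Partition:
    """Label each cluster by majority vote over its members' product strings.

    Empty products and configured stop-words do not vote; ties go to the
    lexicographically smallest product; a cluster with no votes is labelled
    ``cluster_<id>``.
    """
    for c in partition.clusters:
        votes = Counter(
            gene_products[pid] for pid in c.members
            if gene_products.get(pid) and gene_products[pid].lower() not in stopwords
        )
        if votes:
            top = max(votes.values())
            c.label = min(p for p, n in votes.items() if n == top)
        else:
            c.label = f"cluster_{c.cluster_id}"
    return partition
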