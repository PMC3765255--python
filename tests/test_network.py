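"""Context-graph construction, co-occurrence counting, dereplication, export."""
import io

import networkx as nx
import numpy as np
import pytest

from genectx.cluster import cluster_sequences
from genectx.genome import GeneRecord
from genectx.neighborhood import (AnnotatedNeighborhood, Neighborhood,
                                  OperonBlock)
from genectx.network import (build_context_graph, cooccurrence_fraction,
                             dereplicate_neighborhoods, export_graph)
from genectx.simulate import mutate_to_identity


def _gene(i, strand="+", genome="g", start=None):
    s = start if start is not None else 100 + i * 400
    return GeneRecord(genome, genome, i, s, s + 299, strand, f"{genome}:{i}")


def _ann(labels_order, genome="g", query_pos=0, divergent=(), extra_labels=None):
    """Minimal AnnotatedNeighborhood with an all-+ operon of given labels."""
    genes = [_gene(i, genome=genome) for i in range(len(labels_order))]
    qpid = genes[query_pos].pid
    nb = Neighborhood(qpid, genome, genome, 5, genes,
                      list(range(-query_pos, len(genes) - query_pos)))
    labels = {g.pid: lab for g, lab in zip(genes, labels_order)}
    labels.update(extra_labels or {})
    operon = OperonBlock(genes, qpid, 0)
    sig = tuple((labels[g.pid], "+") for g in genes)
    return AnnotatedNeighborhood(nb, labels, operon, list(divergent), sig)


class TestBuildContextGraph:
    def test_consecutive_pair_counting(self):
        anns = [_ann(["A", "B", "C"], genome="g1"),
                _ann(["A", "B", "D"], genome="g2")]
        graph = build_context_graph(anns)
        assert graph.adjacency_count("A", "B") == 2
        assert graph.adjacency_count("B", "C") == 1
        assert graph.adjacency_count("B", "D") == 1
        assert graph.adjacency_count("A", "C") == 0

    def test_empty_input_empty_graph(self):
        graph = build_context_graph([])
        assert graph.nodes == []

    def test_divergent_pair_gets_undirected_edge_only(self):
        up = _gene(5, "-", genome="g3", start=2100)
        down = _gene(6, "+", genome="g3", start=2550)
        ann = _ann(["ImuA"], genome="g3")
        ann.labels[up.pid] = "LexA"
        ann.labels[down.pid] = "ImuA"
        from genectx.neighborhood import DivergentPair
        ann.divergent.append(DivergentPair(up, down, 150))
        graph = build_context_graph([ann])
        assert graph.divergent_count("LexA", "ImuA") == 1
        assert graph.adjacency_count("LexA", "ImuA") == 0

    def test_support_conservation(self):
        """Directed support sums to the number of consecutive operon pairs."""
        rng = np.random.default_rng(0)
        anns = []
        total_pairs = 0
        for g in range(12):
            k = int(rng.integers(1, 5))
            labels = [f"L{rng.integers(0, 6)}_{i}" for i in range(k)]
            total_pairs += k - 1
            anns.append(_ann(labels, genome=f"g{g}"))
        graph = build_context_graph(anns)
        assert graph.total_adjacency_support() == total_pairs

    def test_permutation_invariant(self):
        anns = [_ann(["A", "B"], genome=f"g{i}") for i in range(6)]
        g1 = build_context_graph(anns)
        g2 = build_context_graph(list(reversed(anns)))
        assert g1.adjacency == g2.adjacency and g1.divergent == g2.divergent


class TestCooccurrence:
    def test_all_and_none(self):
        anns = [_ann(["Q", "T"], genome=f"g{i}") for i in range(5)]
        assert cooccurrence_fraction(anns, ["T"]).fraction == 1.0
        assert cooccurrence_fraction(anns, ["Z"]).fraction == 0.0

    def test_query_gene_itself_excluded(self):
        anns = [_ann(["Q"], genome="g0")]
        assert cooccurrence_fraction(anns, ["Q"]).fraction == 0.0

    def test_zero_neighborhoods_is_error(self):
        with pytest.raises(ValueError):
            cooccurrence_fraction([], ["T"])

    def test_exact_counts_reported(self):
        anns = [_ann(["Q", "T"], genome="g0"), _ann(["Q", "U"], genome="g1"),
                _ann(["Q", "T"], genome="g2")]
        stat = cooccurrence_fraction(anns, ["T"])
        assert (stat.n_with_target, stat.n_neighborhoods) == (2, 3)
        assert float(stat.exact) == pytest.approx(2 / 3)


class TestDereplicate:
    def _ann_with_query_protein(self, genome, prot):
        ann = _ann(["Q", "T"], genome=genome)
        ann.neighborhood.genes[0].protein = prot
        return ann

    def test_strain_duplicates_collapse_to_one(self):
        rng = np.random.default_rng(1)
        base = "".join("ACDEFGHIKLMNPQRSTVWY"[k]
                       for k in rng.integers(0, 20, size=120))
        anns = [self._ann_with_query_protein(f"g{i}",
                                             mutate_to_identity(base, 0.99, i))
                for i in range(10)]
        items = [(a.neighborhood.query_pid, a.neighborhood.genes[0].protein)
                 for a in anns]
        culling = cluster_sequences(items, 95.0, 0.9)
        assert len(dereplicate_neighborhoods(anns, culling)) == 1

    def test_distinct_queries_all_retained(self):
        rng = np.random.default_rng(2)
        anns = []
        for i in range(5):
            prot = "".join("ACDEFGHIKLMNPQRSTVWY"[k]
                           for k in rng.integers(0, 20, size=120))
            anns.append(self._ann_with_query_protein(f"g{i}", prot))
        items = [(a.neighborhood.query_pid, a.neighborhood.genes[0].protein)
                 for a in anns]
        culling = cluster_sequences(items, 95.0, 0.9)
        assert len(dereplicate_neighborhoods(anns, culling)) == 5


class TestExport:
    def _graph(self):
        ann = _ann(["A", "B"], genome="g0")
        return build_context_graph([ann])

    def test_graphml_roundtrip_preserves_counts(self):
        graph = build_context_graph(
            [_ann(["A", "B", "C"], genome=f"g{i}") for i in range(3)])
        g = nx.read_graphml(io.BytesIO(export_graph(graph, "graphml").encode()))
        counts = {(u, v): d["count"] for u, v, d in g.edges(data=True)}
        assert counts == {("A", "B"): 3, ("B", "C"): 3}

    def test_graphml_single_edge(self):
        text = export_graph(self._graph(), "graphml")
        assert text.count("<edge ") == 1

    def test_dot_divergent_edges_get_circular_ends(self):
        from genectx.neighborhood import DivergentPair
        up, down = _gene(5, "-"), _gene(6, "+")
        ann = _ann(["A", "B"], extra_labels={up.pid: "A", down.pid: "B"})
        ann.divergent.append(DivergentPair(up, down, 100))
        dot = export_graph(build_context_graph([ann]), "dot")
        assert "arrowhead=odot" in dot and "arrowtail=odot" in dot

    def test_tsv_kinds(self):
        from genectx.neighborhood import DivergentPair
        up, down = _gene(5, "-"), _gene(6, "+")
        ann = _ann(["A", "B"], extra_labels={up.pid: "A", down.pid: "B"})
        ann.divergent.append(DivergentPair(up, down, 100))
        tsv = export_graph(build_context_graph([ann]), "tsv")
        assert "A\tB\tadjacency\t1" in tsv and "A\tB\tdivergent\t1" in tsv

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="unknown format"):
            export_graph(self._graph(), "json")
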