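"""Window extraction, intergenic gaps, operon refinement, divergent pairs."""
import numpy as np
import pytest

from genectx.cluster import assign_labels, cluster_sequences
from genectx.genome import GeneRecord, GenomeTable
from genectx.neighborhood import (annotate_neighborhood,
                                  detect_divergent_pairs,
                                  extract_neighborhood, find_queries,
                                  infer_operon, intergenic_gap)
from genectx.simulate import generate_pangenome


def _table(spans, circular=False, length=None, genome="g", proteins=None):
    genes = []
    for i, (start, end, strand) in enumerate(spans):
        genes.append(GeneRecord(genome, genome, i, start, end, strand,
                                f"{genome}:{i}",
                                protein=(proteins or {}).get(i)))
    t = GenomeTable(genome, genome, length or max(e for _, e, _ in spans) + 100,
                    circular, genes)
    t.validate()
    return t


def _linear_run(n, gap=20, start=100, strand="+", size=300):
    spans = []
    pos = start
    for _ in range(n):
        spans.append((pos, pos + size - 1, strand))
        pos += size + gap
    return spans


class TestExtractNeighborhood:
    def test_full_window_five_each_side(self):
        table = _table(_linear_run(20))
        nb = extract_neighborhood(table, 10, 5)
        assert [g.index for g in nb.genes] == list(range(5, 16))
        assert nb.offsets == list(range(-5, 6))
        assert nb.query.index == 10

    def test_clipped_at_linear_end(self):
        table = _table(_linear_run(20))
        nb = extract_neighborhood(table, 2, 5)
        assert [g.index for g in nb.genes] == list(range(0, 8))

    def test_circular_wrap_without_duplication(self):
        table = _table(_linear_run(8), circular=True)
        nb = extract_neighborhood(table, 0, 5)
        assert [g.index for g in nb.genes] == [3, 4, 5, 6, 7, 0, 1, 2]
        assert len(nb.genes) == 8

    def test_out_of_range_query(self):
        table = _table(_linear_run(4))
        with pytest.raises(IndexError):
            extract_neighborhood(table, 4, 5)


class TestIntergenicGap:
    def test_arithmetic(self):
        a = GeneRecord("g", "r", 0, 100, 200, "+", "a")
        b = GeneRecord("g", "r", 1, 221, 300, "+", "b")
        assert intergenic_gap(a, b) == 20

    def test_abutting_genes(self):
        a = GeneRecord("g", "r", 0, 100, 200, "+", "a")
        b = GeneRecord("g", "r", 1, 201, 300, "+", "b")
        assert intergenic_gap(a, b) == 0

    def test_overlap_is_negative(self):
        a = GeneRecord("g", "r", 0, 100, 200, "+", "a")
        b = GeneRecord("g", "r", 1, 180, 260, "+", "b")
        assert intergenic_gap(a, b) == -21

    def test_cross_replicon_rejected(self):
        a = GeneRecord("g", "r1", 0, 100, 200, "+", "a")
        b = GeneRecord("g", "r2", 1, 221, 300, "+", "b")
        with pytest.raises(ValueError, match="different replicons"):
            intergenic_gap(a, b)


class TestInferOperon:
    def test_strand_flip_terminates_block(self):
        table = _table([(1, 300, "+"), (321, 600, "+"), (650, 900, "-")])
        nb = extract_neighborhood(table, 1, 5)
        op = infer_operon(nb, 150)
        assert op.pids == ("g:0", "g:1")

    def test_codirectional_window_fully_joined(self):
        table = _table(_linear_run(11, gap=30))
        nb = extract_neighborhood(table, 5, 5)
        assert len(infer_operon(nb, 150).genes) == 11

    def test_gap_threshold_is_strict(self):
        table = _table([(1, 300, "+"), (452, 700, "+")])  # gap 151
        nb = extract_neighborhood(table, 0, 5)
        assert infer_operon(nb, 150).pids == ("g:0",)
        table = _table([(1, 300, "+"), (451, 700, "+")])  # gap 150
        nb = extract_neighborhood(table, 0, 5)
        assert infer_operon(nb, 150).pids == ("g:0", "g:1")

    def test_overlapping_codirectional_joined(self):
        table = _table([(1, 300, "+"), (280, 600, "+")])
        nb = extract_neighborhood(table, 1, 5)
        assert len(infer_operon(nb, 150).genes) == 2

    def test_max_gap_extremes(self):
        table = _table(_linear_run(7, gap=200))
        nb = extract_neighborhood(table, 3, 5)
        assert len(infer_operon(nb, 10**9).genes) == 7
        assert infer_operon(nb, -1).pids == ("g:3",)

    def test_invariant_under_coordinate_reversal(self):
        """Reverse-complementing the replicon leaves the operon unchanged."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 9
            spans = []
            pos = 50
            for _ in range(n):
                size = int(rng.integers(150, 500))
                spans.append((pos, pos + size - 1,
                              "+" if rng.random() < 0.6 else "-"))
                pos += size + int(rng.integers(0, 300))
            table = _table(spans)
            total = spans[-1][1] + 50
            flipped = [(total - e + 1, total - s + 1,
                        "-" if st == "+" else "+") for s, e, st in spans]
            rtable = _table(list(reversed(flipped)), length=total, genome="g")
            q = 4
            fwd = infer_operon(extract_neighborhood(table, q, 5), 150)
            rev = infer_operon(extract_neighborhood(rtable, n - 1 - q, 5), 150)
            fwd_idx = sorted(g.index for g in fwd.genes)
            rev_idx = sorted(n - 1 - g.index for g in rev.genes)
            assert fwd_idx == rev_idx


class TestDivergentPairs:
    def test_head_to_head_reported(self):
        table = _table([(1, 500, "-"), (650, 900, "+")])
        nb = extract_neighborhood(table, 0, 5)
        pairs = detect_divergent_pairs(nb, 300)
        assert len(pairs) == 1 and pairs[0].separation == 149

    def test_convergent_ignored(self):
        table = _table([(1, 500, "+"), (650, 900, "-")])
        nb = extract_neighborhood(table, 0, 5)
        assert detect_divergent_pairs(nb, 300) == []

    def test_window_boundary_strict(self):
        table = _table([(1, 500, "-"), (802, 1100, "+")])  # gap 301
        nb = extract_neighborhood(table, 0, 5)
        assert detect_divergent_pairs(nb, 300) == []


class TestFindQueries:
    def test_planted_queries_recovered_exactly(self, tiny_config):
        tables, truth = generate_pangenome(tiny_config, 4)
        seeds = {"QRY": [("QRY", next(f.ancestral_protein
                                      for f in tiny_config.families
                                      if f.family_id == "QRY"))]}
        found = find_queries(tables, seeds, 30.0, 0.6)
        expected = {pid for pid, (fam, _) in truth.gene_families.items()
                    if fam == "QRY"}
        assert {g.pid for g in found["QRY"]} == expected

    def test_exact_seed_match_is_query(self):
        prot = "MKVLAHWRSTMKVLAHWRST" * 4
        table = _table(_linear_run(1), proteins={0: prot})
        found = find_queries([table], {"fam": [("s1", prot)]})
        assert [g.pid for g in found["fam"]] == ["g:0"]

    def test_empty_genome_set(self):
        assert find_queries([], {"fam": [("s1", "MKVLAHW")]}) == {"fam": []}


class TestAnnotateNeighborhood:
    def _annotated(self, strand="+"):
        rng = np.random.default_rng(4)
        prots = {i: "".join("ACDEFGHIKLMNPQRSTVWY"[k]
                            for k in rng.integers(0, 20, size=90))
                 for i in range(3)}
        spans = [(100, 370, strand), (400, 670, strand), (700, 970, strand)]
        if strand == "-":
            spans = list(reversed([(2000 - e, 2000 - s, strand) for s, e, st in spans]))
        table = _table(spans, proteins=dict(enumerate(prots.values())))
        items = [(g.pid, g.protein) for g in table.genes]
        part = cluster_sequences(items, 30, 0.6)
        labels = {f"g:{i}": lab for i, lab in enumerate(["SRAP", "UmuD", "UmuC"])}
        if strand == "-":
            labels = {f"g:{i}": lab for i, lab in
                      enumerate(["UmuC", "UmuD", "SRAP"])}
        assign_labels(part, labels)
        qidx = 0 if strand == "+" else 2
        nb = extract_neighborhood(table, qidx, 5)
        return annotate_neighborhood(nb, part, max_gap=150)

    def test_signature_on_plus_strand(self):
        ann = self._annotated("+")
        assert ann.signature == (("SRAP", "+"), ("UmuD", "+"), ("UmuC", "+"))

    def test_minus_strand_normalized_to_query_orientation(self):
        """The same operon on the - strand yields the same signature."""
        ann = self._annotated("-")
        assert ann.signature == (("SRAP", "+"), ("UmuD", "+"), ("UmuC", "+"))

    def test_missing_pid_named_in_error(self):
        table = _table(_linear_run(2), proteins={0: "MKVLAHW" * 5,
                                                 1: "MSTKWRH" * 5})
        part = cluster_sequences([("g:0", "MKVLAHW" * 5)], 30, 0.6)
        assign_labels(part, {"g:0": "A"})
        nb = extract_neighborhood(table, 0, 5)
        with pytest.raises(KeyError, match="g:1"):
            annotate_neighborhood(nb, part)

    def test_singleton_operon_signature(self):
        table = _table([(1, 300, "+"), (800, 1100, "-")],
                       proteins={0: "MKVLAHW" * 6, 1: "MSTKWRH" * 6})
        part = cluster_sequences([(g.pid, g.protein) for g in table.genes], 30, 0.6)
        assign_labels(part, {"g:0": "A", "g:1": "B"})
        ann = annotate_neighborhood(extract_neighborhood(table, 0, 5), part)
        assert ann.signature == (("A", "+"),)
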