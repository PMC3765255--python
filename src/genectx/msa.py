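"""Alignment-conservation analysis: consensus categories, invariant columns,
information content, and column-to-residue mapping.

Consumes (never builds) protein multiple sequence alignments. Per-column
consensus categories follow the standard alignment-coloring scheme: a column
is *absolute* when a single residue occupies every row, else it is labelled
with the first residue class -- aromatic, hydrophobic, polar, big -- whose
summed frequency reaches the consensus threshold (default 0.85). The classes
overlap (F, Y, H are aromatic and hydrophobic), so precedence is
most-specific-first. Gaps count in the consensus denominator, so a heavily
gapped column cannot reach consensus; information content, by logo
convention, renormalizes over the non-gap residues.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .genome import PROTEIN_ALPHABET
from .io import read_fasta

GAP = "-"

#: Residue classes of the consensus scheme, in precedence order.
CATEGORY_SETS: dict[str, frozenset[str]] = {
    "a": frozenset("FYH"),              # aromatic
    "h": frozenset("ACFGHILMTVWY"),     # hydrophobic
    "polar": frozenset("CDEHKNQRST"),
    "big": frozenset("QRKEILMWYF"),
}

MAX_BITS = math.log2(20)


@dataclass
class MSA:
    """A protein multiple alignment: equal-length rows with unique ids."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids")
        for rid, seq in self.rows:
            bad = set(seq) - PROTEIN_ALPHABET - {GAP}
            if bad:
                raise ValueError(f"row {rid!r}: invalid characters {sorted(bad)}")

    @classmethod
    def from_fasta(cls, text: str) -> "MSA":
        return cls(read_fasta(text))

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, col: int) -> str:
        """Column characters (1-based column index)."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        return "".join(seq[col - 1] for _, seq in self.rows)

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(f"no row {row_id!r}")


@dataclass
class ColumnAnnotation:
    column: int          # 1-based
    category: str        # "absolute" | "a" | "h" | "polar" | "big" | "none"
    residue: str         # top residue of the column ("" for all-gap)
    fraction: float      # frequency of the assigned class (or top residue)


def column_composition(msa: MSA, col: int) -> dict[str, float]:
    """Residue (and gap) frequencies of a column over the full row count."""
    chars = msa.column(col)
    n = len(chars)
    return {ch: cnt / n for ch, cnt in sorted(Counter(chars).items())}


def consensus_annotation(msa: MSA, threshold: float = 0.85) -> list[ColumnAnnotation]:
    """Per-column consensus categories at the given threshold.

    Precedence: absolute (one residue at fraction 1.0; X breaks
    absoluteness) > aromatic > hydrophobic > polar > big > none. A class
    fires when the summed fraction of its residues reaches the threshold;
    gaps and X dilute every class.
    """
    out = []
    for col in range(1, msa.length + 1):
        chars = msa.column(col)
        counts = Counter(chars)
        n = len(chars)
        residues = {ch: c for ch, c in counts.items() if ch != GAP}
        top, top_n = ("", 0)
        if residues:
            top = min(ch for ch, c in residues.items() if c == max(residues.values()))
            top_n = residues[top]
        if len(residues) == 1 and top != "X" and counts[top] == n:
            out.append(ColumnAnnotation(col, "absolute", top, 1.0))
            continue
        for name, members in CATEGORY_SETS.items():
            frac = sum(c for ch, c in residues.items() if ch in members) / n
            if frac >= threshold:
                out.append(ColumnAnnotation(col, name, top, frac))
                break
        else:
            out.append(ColumnAnnotation(col, "none", top, top_n / n))
    return out


def absolutely_conserved_positions(msa: MSA) -> list[tuple[int, str]]:
    """Columns (1-based) where a single residue occupies every row, no gaps."""
    return [(ann.column, ann.residue)
            for ann in consensus_annotation(msa)
            if ann.category == "absolute"]


def information_content(msa: MSA) -> list[float]:
    """Per-column logo height: log2(20) minus the Shannon entropy of the
    gap-excluded residue distribution; all-gap columns report 0 bits."""
    out = []
    for col in range(1, msa.length + 1):
        counts = Counter(ch for ch in msa.column(col) if ch != GAP)
        total = sum(counts.values())
        if total == 0:
            out.append(0.0)
            continue
        entropy = -sum((c / total) * math.log2(c / total) for c in counts.values())
        out.append(max(MAX_BITS - entropy, 0.0))
    return out


def map_column_to_residue(msa: MSA, row_id: str, col: int) -> int:
    """1-based residue index of alignment column ``col`` in the ungapped row."""
    seq = msa.row(row_id)
    if not 1 <= col <= msa.length:
        raise IndexError(f"column {col} out of range 1..{msa.length}")
    if seq[col - 1] == GAP:
        raise ValueError(f"column {col} not represented in row {row_id!r}")
    return sum(1 for ch in seq[:col] if ch != GAP)


def consensus_line(annotations: Sequence[ColumnAnnotation]) -> str:
    """One character per column: the residue for absolute columns, the class
    letter (a/h/p/b) otherwise, '.' for none."""
    short = {"a": "a", "h": "h", "polar": "p", "big": "b", "none": "."}
    return "".join(ann.residue if ann.category == "absolute"
                   else short[ann.category] for ann in annotations)


def render_annotated_alignment(msa: MSA, threshold: float = 0.85,
                               width: int = 60) -> str:
    """Plain-text rendering: alignment blocks with the consensus line below."""
    anns = consensus_annotation(msa, threshold)
    cons = consensus_line(anns)
    name_w = max(len(rid) for rid, _ in msa.rows)
    name_w = max(name_w, len("consensus"))
    blocks = []
    for lo in range(0, msa.length, width):
        hi = min(lo + width, msa.length)
        lines = [f"{rid:<{name_w}}  {seq[lo:hi]}" for rid, seq in msa.rows]
        lines.append(f"{'consensus':<{name_w}}  {cons[lo:hi]}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
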