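"""Core annotation records: one CDS, and the ordered gene list of a replicon.

Coordinates are 1-based and inclusive at both ends (the NCBI protein-table
convention). No half-open conversion is exposed anywhere in the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-")

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues allowed in a stored protein sequence (X = unknown residue).
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")


class GenomeError(ValueError):
    """Invalid gene or replicon data."""


@dataclass
class GeneRecord:
    """One annotated protein-coding gene on a replicon.

    Parameters
    ----------
    genome_id : str
        Identifier of the genome the replicon belongs to.
    replicon_id : str
        Identifier of the chromosome/plasmid/contig.
    index : int
        0-based ordinal position on the replicon, by ascending start.
    start, end : int
        1-based nucleotide coordinates, both inclusive; ``start <= end``.
    strand : str
        ``"+"`` or ``"-"``.
    pid : str
        Protein identifier, unique within a dataset.
    gene_name, product : str
        Gene symbol and free-text annotation; empty string when absent.
    protein : str or None
        Amino-acid sequence over the 20 standard residues plus X.
    """

    genome_id: str
    replicon_id: str
    index: int
    start: int
    end: int
    strand: str
    pid: str
    gene_name: str = ""
    product: str = ""
    protein: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise GenomeError(
                f"gene {self.pid!r}: require 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )
        if self.strand not in STRANDS:
            raise GenomeError(f"gene {self.pid!r}: bad strand {self.strand!r}")
        if not self.pid:
            raise GenomeError("empty pid")
        if self.protein is not None and not set(self.protein) <= PROTEIN_ALPHABET:
            bad = sorted(set(self.protein) - PROTEIN_ALPHABET)
            raise GenomeError(f"gene {self.pid!r}: non-residue characters {bad}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeTable:
    """The ordered gene list of one replicon.

    ``genes`` is sorted strictly by (start, end); each record's ``index``
    equals its list position and all pids are distinct.
    """

    genome_id: str
    replicon_id: str
    replicon_length: int
    circular: bool
    genes: list[GeneRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        """Raise :class:`GenomeError` if any table invariant is violated."""
        keys = [(g.start, g.end) for g in self.genes]
        if keys != sorted(keys) or len(set(keys)) != len(keys):
            raise GenomeError(
                f"{self.replicon_id}: genes not strictly sorted by (start, end)"
            )
        for pos, g in enumerate(self.genes):
            if g.index != pos:
                raise GenomeError(
                    f"{self.replicon_id}: gene {g.pid} has index {g.index}, "
                    f"expected {pos}"
                )
        pids = [g.pid for g in self.genes]
        if len(set(pids)) != len(pids):
            raise GenomeError(f"{self.replicon_id}: duplicate pids")

    def reindex(self) -> None:
        """Sort genes by (start, end) and rewrite their ``index`` fields."""
        self.genes.sort(key=lambda g: (g.start, g.end))
        for pos, g in enumerate(self.genes):
            g.index = pos
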