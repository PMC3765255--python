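"""Readers and writers for the formats the pipeline touches.

PTT protein tables (the NCBI tab-separated per-replicon CDS listing),
GenBank flat files (CDS features only, for WGS records), plain and aligned
FASTA. All text I/O is UTF-8; writers emit Unix newlines.
"""
from __future__ import annotations

import io as _io
import logging
import re
import warnings

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .genome import GeneRecord, GenomeTable

log = logging.getLogger(__name__)

_PTT_HEADER = "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct"
# U+2212 minus occasionally appears in strand columns of third-party tables
_STRAND_NORM = {"+": "+", "-": "-", "−": "-"}


class PttParseError(ValueError):
    """Malformed PTT document; the message names the offending line."""


class OriginSpanningGeneError(ValueError):
    """CDS wrapping the origin of a circular replicon (unsupported).

    The neighborhood logic indexes genes by ordinal position along the
    coordinate axis, and origin-spanning genes have no single well-ordered
    coordinate span, so they are rejected rather than silently split.
    """


def _blank(token: str) -> str:
    return "" if token == "-" else token


def parse_ptt(text: str, genome_id: str, *, replicon_id: str | None = None,
              circular: bool = False) -> GenomeTable:
    """Parse an NCBI PTT protein table into a :class:`GenomeTable`.

    Layout: a title line (often ending ``- 1..LENGTH``), an ``N proteins``
    count line, the tab-separated column header, then one row per CDS with
    columns Location (``start..end``), Strand, Length, PID, Gene, Synonym,
    Code, COG, Product. ``-`` fields map to empty strings; the Length column
    is ignored in favour of coordinate arithmetic. Rows are re-sorted by
    start, and a declared/observed protein-count mismatch is a warning, not
    a failure.
    """
    lines = text.splitlines()
    if len(lines) < 3:
        raise PttParseError("PTT document shorter than 3 lines")
    title = lines[0]
    m = re.search(r"(\d+)\s*\.\.\s*(\d+)\s*$", title)
    replicon_length = int(m.group(2)) if m else 0
    m = re.match(r"\s*(\d+)\s+proteins?\s*$", lines[1])
    if not m:
        raise PttParseError(f"line 2: expected 'N proteins', got {lines[1]!r}")
    declared = int(m.group(1))

    genes: list[GeneRecord] = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        if "\t" in line:
            fields = line.split("\t")
        else:
            # tolerate space-separated renderings; product is everything
            # after the 8th column
            parts = line.split()
            fields = parts[:8] + [" ".join(parts[8:])]
        if len(fields) < 9:
            raise PttParseError(f"line {lineno}: expected 9 columns, got {len(fields)}")
        loc, strand_tok = fields[0].strip(), fields[1].strip()
        if ".." not in loc:
            raise PttParseError(f"line {lineno}: malformed Location {loc!r}")
        left, _, right = loc.partition("..")
        try:
            start, end = int(left), int(right)
        except ValueError:
            raise PttParseError(f"line {lineno}: malformed Location {loc!r}") from None
        strand = _STRAND_NORM.get(strand_tok)
        if strand is None:
            raise PttParseError(f"line {lineno}: bad strand {strand_tok!r}")
        genes.append(GeneRecord(
            genome_id=genome_id,
            replicon_id=replicon_id or genome_id,
            index=0,
            start=start,
            end=end,
            strand=strand,
            pid=fields[3].strip(),
            gene_name=_blank(fields[4].strip()),
            product=_blank(fields[8].strip()),
        ))
    if len(genes) != declared:
        warnings.warn(
            f"{genome_id}: PTT declares {declared} proteins, parsed {len(genes)}",
            stacklevel=2,
        )
    if not replicon_length and genes:
        replicon_length = max(g.end for g in genes)
    table = GenomeTable(
        genome_id=genome_id,
        replicon_id=replicon_id or genome_id,
        replicon_length=replicon_length,
        circular=circular,
        genes=genes,
    )
    table.reindex()
    table.validate()
    return table


def write_ptt(table: GenomeTable, *, title: str | None = None) -> str:
    """Render a :class:`GenomeTable` as a PTT document."""
    head = title or f"{table.replicon_id} - 1..{table.replicon_length}"
    out = [head, f"{len(table.genes)} proteins", _PTT_HEADER]
    for g in table.genes:
        aa_len = max((g.length_nt - 3) // 3, 0)
        out.append("\t".join([
            f"{g.start}..{g.end}", g.strand, str(aa_len), g.pid,
            g.gene_name or "-", g.pid, "-", "-", g.product or "-",
        ]))
    return "\n".join(out) + "\n"


def _is_origin_spanning(location, strand: str) -> bool:
    if not isinstance(location, CompoundLocation):
        return False
    parts = list(location.parts)
    if strand == "-":
        parts = parts[::-1]
    starts = [int(p.start) for p in parts]
    return any(b < a for a, b in zip(starts, starts[1:]))


def parse_genbank_cds(text: str, *, genome_id: str | None = None) -> GenomeTable:
    """Extract CDS features from one GenBank record into a :class:`GenomeTable`.

    Only CDS features carrying a ``translation`` become genes;
    ``complement(...)`` locations yield strand ``-``; compound (join)
    locations use the outermost span; the circular flag is read from the
    LOCUS line. A CDS without a ``protein_id`` is assigned the synthetic pid
    ``<replicon>:<index>`` (logged). A gene spanning the origin of a
    circular replicon raises :class:`OriginSpanningGeneError`.
    """
    record = SeqIO.read(_io.StringIO(text), "genbank")
    replicon_id = record.id if record.id != "<unknown id>" else record.name
    gid = genome_id or replicon_id
    circular = record.annotations.get("topology", "linear") == "circular"
    replicon_length = len(record.seq) or int(
        re.search(r"\s(\d+)\s+bp", text.splitlines()[0]).group(1))

    genes: list[GeneRecord] = []
    n_cds = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        translation = feat.qualifiers.get("translation", [None])[0]
        if translation is None:
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        if _is_origin_spanning(feat.location, strand):
            if circular:
                raise OriginSpanningGeneError(
                    f"{replicon_id}: CDS at {feat.location} spans the origin "
                    "of a circular replicon; not supported"
                )
            raise OriginSpanningGeneError(
                f"{replicon_id}: CDS at {feat.location} has out-of-order "
                "location parts"
            )
        pid = feat.qualifiers.get("protein_id", [None])[0]
        if pid is None:
            pid = f"{replicon_id}:{n_cds}"
            log.info("CDS without protein_id assigned synthetic pid %s", pid)
        genes.append(GeneRecord(
            genome_id=gid,
            replicon_id=replicon_id,
            index=0,
            start=int(feat.location.start) + 1,
            end=int(feat.location.end),
            strand=strand,
            pid=pid,
            gene_name=feat.qualifiers.get("gene", [""])[0],
            product=feat.qualifiers.get("product", [""])[0],
            protein=translation.upper(),
        ))
        n_cds += 1
    table = GenomeTable(
        genome_id=gid,
        replicon_id=replicon_id,
        replicon_length=replicon_length,
        circular=circular,
        genes=genes,
    )
    table.reindex()
    table.validate()
    return table


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Read FASTA text into ``[(id, sequence), ...]``; sequences uppercased."""
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], *, width: int = 60) -> str:
    """Render ``(id, sequence)`` pairs as FASTA with fixed line wrapping."""
    out = []
    for rid, seq in records:
        out.append(f">{rid}")
        out.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"
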