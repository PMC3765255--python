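"""Seeded synthetic pangenomes with planted gene-context structure.

The generator emulates the kind of survey input the neighborhood pipeline is
built for: many bacterial replicons, a handful of protein families arranged
into operon templates planted at controlled prevalence, homologs diverged to
a controlled percent identity, and unrelated background genes. Every stage
downstream (query finding, clustering, operon refinement, network building,
co-occurrence) can therefore be tested against exact ground truth.

Geometry defaults place the two intergenic-gap regimes well apart: gaps
inside a planted operon average 30 bp and never exceed 100 bp, while genes
in different transcription units are at least 400 bp apart, so the 150 bp
operon-joining threshold sits safely between them.

A genome draws at most one template from each *template group* (the draw is
categorical over the group's prevalences); a singleton group is an ordinary
independent Bernoulli plant. Grouping lets a query family be planted either
inside its context operon (with the configured prevalence) or solo, which is
what a fixed context-association fraction among query-bearing genomes means.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .align import align_pair
from .cluster import neighbor_test
from .genome import AMINO_ACIDS, GeneRecord, GenomeTable
from .io import write_fasta, write_ptt

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass
class FamilyModel:
    """One protein family: an ancestral sequence and its role in the plant."""

    family_id: str
    ancestral_protein: str
    role: str  # query | context | background

    def __post_init__(self):
        if self.role not in ("query", "context", "background"):
            raise ValueError(f"bad role {self.role!r}")
        if not set(self.ancestral_protein) <= set(AMINO_ACIDS):
            raise ValueError(f"{self.family_id}: ancestor must use the 20 standard residues")


@dataclass
class OperonTemplate:
    """An ordered multi-gene context planted as one transcription unit.

    ``genes`` lists (family_id, relative strand); ``prevalence`` is the
    probability a genome carries this template (within its group, see module
    docstring). ``divergent_partner`` optionally plants one extra family
    head-to-head with the operon's 5' end across a short (<=150 bp) gap, the
    bidirectional-promoter arrangement drawn with circular edge ends in
    contextual network figures.
    """

    template_id: str
    genes: list[tuple[str, str]]
    prevalence: float
    gap_mean: float = 30.0
    gap_max: int = 100
    divergent_partner: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{self.template_id}: prevalence outside [0, 1]")
        if self.gap_mean < 0 or self.gap_max < 0:
            raise ValueError(f"{self.template_id}: negative gap parameters")
        if not self.genes:
            raise ValueError(f"{self.template_id}: empty template")


@dataclass
class PangenomeConfig:
    families: list[FamilyModel]
    templates: list[OperonTemplate]
    n_genomes: int = 200
    template_groups: list[list[str]] | None = None
    background_genes: tuple[int, int] = (12, 20)
    background_length: tuple[int, int] = (100, 300)
    identity_range: tuple[float, float] = (0.65, 0.95)
    between_gap: tuple[int, int] = (400, 1000)
    divergent_gap: tuple[int, int] = (30, 150)
    replicon_length: int | None = None
    genome_prefix: str = "g"

    def groups(self) -> list[list[OperonTemplate]]:
        by_id = {t.template_id: t for t in self.templates}
        if self.template_groups is None:
            return [[t] for t in self.templates]
        grouped = [[by_id[tid] for tid in grp] for grp in self.template_groups]
        listed = {t.template_id for grp in grouped for t in grp}
        grouped += [[t] for t in self.templates if t.template_id not in listed]
        return grouped

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not self.templates:
            raise ValueError("at least one template required")
        fids = [f.family_id for f in self.families]
        if len(set(fids)) != len(fids):
            raise ValueError("family_ids not unique")
        roles = {f.family_id: f.role for f in self.families}
        for t in self.templates:
            used = [fid for fid, _ in t.genes]
            if t.divergent_partner:
                used.append(t.divergent_partner)
            unknown = [f for f in used if f not in roles]
            if unknown:
                raise ValueError(f"{t.template_id}: unknown families {unknown}")
            if not any(roles[fid] == "query" for fid, _ in t.genes):
                raise ValueError(f"{t.template_id}: no query-role family")
        for grp in self.groups():
            if sum(t.prevalence for t in grp) > 1.0 + 1e-9:
                raise ValueError("template group prevalences sum to > 1")


@dataclass
class PlantedOperon:
    """Ground truth for one planted template instance."""

    genome_id: str
    template_id: str
    pids: tuple[str, ...]          # core genes, coordinate order
    query_pids: tuple[str, ...]
    extent_pids: dict[str, tuple[str, ...]]  # query pid -> its co-directional run
    partner_pid: str | None = None


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the pipeline must recover."""

    gene_families: dict[str, tuple[str, str]] = field(default_factory=dict)  # pid -> (family, template)
    template_instances: dict[str, list[str]] = field(default_factory=dict)
    realized_prevalence: dict[str, float] = field(default_factory=dict)
    operons: list[PlantedOperon] = field(default_factory=list)
    divergent_pairs: list[tuple[str, str, str]] = field(default_factory=list)  # genome, -pid, +pid


def mutate_to_identity(seq: str, target_identity: float,
                       seed: int | np.random.Generator) -> str:
    """Substitute exactly ``round(len * (1 - identity))`` positions.

    Positions are chosen uniformly without replacement; each substitution is
    drawn uniformly from the 19 non-identical standard residues.
    Deterministic given the seed (or generator state).
    """
    if not 0.0 <= target_identity <= 1.0:
        raise ValueError("target_identity outside [0, 1]")
    if len(seq) < 1:
        raise ValueError("empty sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = int(round(len(seq) * (1.0 - target_identity)))
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        current = out[pos]
        alt = AMINO_ACIDS.replace(current, "")
        out[pos] = alt[int(rng.integers(len(alt)))]
    return "".join(out)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=length))


def _within_gap(rng: np.random.Generator, t: OperonTemplate) -> int:
    return int(min(rng.exponential(t.gap_mean), t.gap_max))


def generate_pangenome(config: PangenomeConfig,
                       seed: int) -> tuple[list[GenomeTable], SyntheticTruth]:
    """Generate ``n_genomes`` replicons with planted contexts and truth.

    Per-genome random streams are derived as ``seed + 1 + genome_index`` so
    output is reproducible regardless of generation order.
    """
    config.validate()
    families = {f.family_id: f for f in config.families}
    groups = config.groups()
    truth = SyntheticTruth()
    counts = {t.template_id: 0 for t in config.templates}
    tables: list[GenomeTable] = []

    for gidx in range(config.n_genomes):
        genome_id = f"{config.genome_prefix}{gidx:04d}"
        rng = np.random.default_rng(seed + 1 + gidx)
        chosen: list[OperonTemplate] = []
        for grp in groups:
            u = rng.random()
            cum = 0.0
            for t in grp:
                cum += t.prevalence
                if u < cum:
                    chosen.append(t)
                    break
        n_bg = int(rng.integers(config.background_genes[0],
                                config.background_genes[1] + 1))
        segments: list[OperonTemplate | None] = list(chosen) + [None] * n_bg
        order = rng.permutation(len(segments))

        cursor = int(rng.integers(1, 500))
        genes: list[GeneRecord] = []
        pid_counter = 0

        def place(protein: str, strand: str, product: str,
                  gap_after: int) -> str:
            nonlocal cursor, pid_counter
            nt = 3 * len(protein) + 3
            pid = f"{genome_id}:{pid_counter:04d}"
            genes.append(GeneRecord(
                genome_id=genome_id, replicon_id=genome_id,
                index=pid_counter, start=cursor, end=cursor + nt - 1,
                strand=strand, pid=pid, product=product, protein=protein,
            ))
            pid_counter += 1
            cursor += nt + gap_after
            return pid

        def between() -> int:
            return int(rng.integers(config.between_gap[0],
                                    config.between_gap[1] + 1))

        for si in order:
            t = segments[si]
            if t is None:
                aa = int(rng.integers(config.background_length[0],
                                      config.background_length[1] + 1))
                place(_random_protein(rng, aa),
                      "+" if rng.random() < 0.5 else "-",
                      "hypothetical protein", between())
                continue
            counts[t.template_id] += 1
            truth.template_instances.setdefault(genome_id, []).append(t.template_id)
            flip = rng.random() < 0.5

            def diverged(fid: str) -> str:
                ident = rng.uniform(*config.identity_range)
                return mutate_to_identity(families[fid].ancestral_protein, ident, rng)

            core = t.genes if not flip else [
                (fid, "+" if rel == "-" else "-") for fid, rel in reversed(t.genes)]
            entries: list[tuple[str, str, bool]] = [
                (fid, rel, False) for fid, rel in core]
            if t.divergent_partner:
                if not flip:
                    entries.insert(0, (t.divergent_partner, "-", True))
                else:
                    entries.append((t.divergent_partner, "+", True))

            core_pids: list[str] = []
            partner_pid: str | None = None
            strands: list[str] = []
            for pos, (fid, strand, is_partner) in enumerate(entries):
                last = pos == len(entries) - 1
                if last:
                    gap = between()
                elif is_partner or entries[pos + 1][2]:
                    gap = int(rng.integers(config.divergent_gap[0],
                                           config.divergent_gap[1] + 1))
                else:
                    gap = _within_gap(rng, t)
                pid = place(diverged(fid), strand, fid, gap)
                truth.gene_families[pid] = (fid, t.template_id)
                if is_partner:
                    partner_pid = pid
                else:
                    core_pids.append(pid)
                    strands.append(strand)

            query_pids = tuple(
                pid for pid in core_pids
                if families[truth.gene_families[pid][0]].role == "query")
            # a query's plantable operon extent is its maximal co-directional
            # run inside the core (planted core gaps never exceed gap_max)
            extents: dict[str, tuple[str, ...]] = {}
            for qp in query_pids:
                qi = core_pids.index(qp)
                lo = qi
                while lo > 0 and strands[lo - 1] == strands[qi]:
                    lo -= 1
                hi = qi
                while hi < len(core_pids) - 1 and strands[hi + 1] == strands[qi]:
                    hi += 1
                extents[qp] = tuple(core_pids[lo:hi + 1])
            truth.operons.append(PlantedOperon(
                genome_id, t.template_id, tuple(core_pids), query_pids,
                extents, partner_pid))
            if partner_pid is not None:
                neighbor = core_pids[0] if not flip else core_pids[-1]
                if not flip:
                    truth.divergent_pairs.append((genome_id, partner_pid, neighbor))
                else:
                    truth.divergent_pairs.append((genome_id, neighbor, partner_pid))

        last_end = genes[-1].end if genes else 1
        length = last_end + int(rng.integers(200, 501))
        if config.replicon_length is not None:
            if last_end > config.replicon_length:
                raise ValueError(
                    f"{genome_id}: genes extend to {last_end} bp, beyond the "
                    f"configured replicon length {config.replicon_length}; "
                    "configure a larger replicon")
            length = config.replicon_length
        table = GenomeTable(genome_id=genome_id, replicon_id=genome_id,
                            replicon_length=length, circular=False, genes=genes)
        table.validate()
        tables.append(table)

    truth.realized_prevalence = {
        tid: n / config.n_genomes for tid, n in counts.items()}
    return tables, truth


def emit_genomes(tables: list[GenomeTable], truth: SyntheticTruth,
                 out_dir: str | Path, *, config: PangenomeConfig | None = None,
                 seed: int | None = None, overwrite: bool = False) -> None:
    """Write one PTT + one protein FASTA per genome, truth.tsv and a manifest.

    Re-parsing the PTT/FASTA pair with :mod:`genectx.io` reproduces the
    in-memory tables exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    for table in tables:
        (out / f"{table.genome_id}.ptt").write_text(write_ptt(table))
        recs = [(g.pid, g.protein) for g in table.genes if g.protein]
        (out / f"{table.genome_id}.faa").write_text(write_fasta(recs))
    rows = ["genome_id\tpid\tfamily_id\ttemplate_id"]
    for pid in sorted(truth.gene_families):
        fam, tid = truth.gene_families[pid]
        rows.append(f"{pid.split(':')[0]}\t{pid}\t{fam}\t{tid}")
    (out / "truth.tsv").write_text("\n".join(rows) + "\n")
    manifest = {"seed": seed}
    if config is not None:
        # json round-trip turns tuples into lists for YAML serialization
        manifest["config"] = json.loads(json.dumps(dataclasses.asdict(config)))
    (out / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False))


def _ancestors(rng: np.random.Generator, spec: dict[str, tuple[int, str]],
               identity: float = 30.0, coverage: float = 0.6
               ) -> list[FamilyModel]:
    """Draw mutually non-linkable family ancestors.

    A candidate ancestor is redrawn while it would pass the neighbor test
    against any already-drawn ancestor at the clustering thresholds, so the
    planted families are separable by construction (short random proteins
    can otherwise collide by chance).
    """
    out: list[FamilyModel] = []
    for fid, (length, role) in spec.items():
        while True:
            cand = _random_protein(rng, length)
            if all(not neighbor_test(align_pair(cand, f.ancestral_protein),
                                     identity, coverage) for f in out):
                break
        out.append(FamilyModel(fid, cand, role))
    return out


def sos_study_config(n_genomes: int = 200, *,
                     srap_prevalence: float = 0.65,
                     imubc_prevalence: float = 0.25,
                     family_seed: int = 2013,
                     divergent_partner: str | None = None) -> PangenomeConfig:
    """The default study conditions: an SOS-like pangenome.

    Two query families (an SRAP-like ~240 aa domain and an ImuB-C-like 80 aa
    domain) are planted in every genome, each either inside its context
    operon (translesion-polymerase partners, at the given prevalence) or
    solo. Family ancestors are fixed by ``family_seed`` so the families are
    part of the study definition, not of the per-run randomness.
    """
    rng = np.random.default_rng(family_seed)
    families = _ancestors(rng, {
        "SRAP": (240, "query"),
        "ImuB_C": (80, "query"),
        "UmuC": (150, "context"),
        "UmuD": (120, "context"),
        "DinB": (150, "context"),
        "LexA": (120, "context"),
    })
    templates = [
        OperonTemplate("srap_umu", [("SRAP", "+"), ("UmuD", "+"), ("UmuC", "+")],
                       srap_prevalence, divergent_partner=divergent_partner),
        OperonTemplate("srap_solo", [("SRAP", "+")], 1.0 - srap_prevalence),
        OperonTemplate("imubc_dinb", [("ImuB_C", "+"), ("DinB", "+"), ("LexA", "+")],
                       imubc_prevalence),
        OperonTemplate("imubc_solo", [("ImuB_C", "+")], 1.0 - imubc_prevalence),
    ]
    return PangenomeConfig(
        families=families, templates=templates, n_genomes=n_genomes,
        template_groups=[["srap_umu", "srap_solo"], ["imubc_dinb", "imubc_solo"]],
    )
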