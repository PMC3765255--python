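# Methods

`genectx` re-implements, as a tested pipeline, the comparative-genomics
procedure by which conserved gene neighborhoods around a query protein
family are collected from bacterial genome annotations, the neighbor
proteins are clustered into families, the windows are refined into operons,
and the recurring arrangements are summarized as a contextual association
network with co-occurrence statistics. A separate conservation layer
annotates protein multiple alignments (consensus categories, invariant
columns, information content) and maps alignment columns onto the residue
numbering of a reference sequence such as a solved structure's chain.

## Neighborhood model

The unit of analysis is the window of ±k genes around each query gene
(default k = 5), read from a PTT protein table or from the CDS features of
a GenBank record. Coordinates are 1-based and inclusive throughout, the PTT
convention; genes are ordered by start coordinate, and the window indexes
genes ordinally, clipping at the ends of linear replicons and wrapping
(without duplication) on circular ones. Genes spanning the origin of a
circular replicon are rejected outright: ordinal indexing has no
well-defined place for them and silently splitting them would corrupt gap
arithmetic.

Within a window, the operon containing the query is the maximal run of
consecutive genes that share the query's strand and whose successive
intergenic gaps (`start(b) − end(a) − 1`) do not exceed `max_gap`
(default 150 bp). Distance is used as the standard proxy for "shares a
promoter"; no promoter model is attempted. Overlapping co-directional genes
(negative gap) are always joined, since overlap implies translational
coupling. Head-to-head pairs on opposite strands (− then + in coordinate
order) within `bidir_window` (default 300 bp) are reported separately as
candidate bidirectional-promoter arrangements; convergent pairs never are.

Operon signatures are normalized to read 5′→3′ along the query's strand, so
instances of the same operon on opposite genomic strands compare equal.
When two query genes share one operon, one neighborhood is reported per
query gene; neighborhoods are never merged.

## Similarity clustering

Neighbor proteins are grouped by single-linkage clustering over a pairwise
neighbor test: percent identity ≥ I (default 30) and alignment coverage ≥ L
(default 0.6) on *both* sequences. Requiring coverage on both sequences
prevents promiscuous domain-level linkage. Defaults I = 30 / L = 0.6 for
family clustering and I = 95 / L = 0.9 for culling near-identical sequences
are package choices, exposed in the configuration.

Pairwise similarity comes from an exact affine-gap Smith–Waterman (Gotoh)
alignment, BLOSUM62, gap of length *g* costing 11 + *g* (the BLAST
convention). Because percent identity and coverage depend on *which*
co-optimal alignment is reported, tie-breaking is pinned: the end cell is
the maximum-score cell with the largest (i, j) in row-major order (so
score-neutral extensions are kept), the traceback prefers diagonal over
vertical over horizontal moves, and gap runs are closed as early as
possible. Identity is counted over residue–residue columns only (gap
columns count in neither numerator nor denominator); `X` aligns by its
BLOSUM62 row but never counts as identical. The kernel is numba-compiled;
its results are checked in the test suite against an independently written
pure-Python DP and against Biopython's `PairwiseAligner` scores.

By default every pair is aligned. For survey-scale inputs an optional
candidate screen restricts the exact DP to pairs sharing at least one exact
k-mer (the pipeline uses k = 5), the same candidate-generation idea that
BLAST-based clustering tools rely on: the screen can only prune pairs,
never add them, so clusters can only be refined, never wrongly merged. Two
sequences above 30% identity over 60% of their length share a 5-mer with
overwhelming probability once identity is moderately high; truly borderline
pairs can in principle be missed, which is why the screen is off by default
and the exactness contract is tested with it off. Within one pipeline run
pair similarities are cached and reused across the query-finding,
neighbor-clustering and culling stages; similarities do not depend on the
thresholds, so the reuse is exact.

Cluster representatives are the longest member (ties to the smallest pid);
cluster ids are assigned by (size desc, representative pid); labels are a
majority vote over member product strings, ignoring stop-words like
"hypothetical protein".

## Queries, dereplication, network, co-occurrence

A gene is a query for a family iff it lands in the same single-linkage
cluster as one of that family's seed sequences when seeds and all genome
proteins are clustered together. Before computing statistics, query
proteins are culled at 95%/0.9 and one neighborhood is kept per
near-identity cluster (the representative's), so heavily sequenced strains
do not dominate counts.

The contextual network has gene-family labels as nodes. Each consecutive
label pair inside an operon contributes support to a directed edge (5′
family → 3′ family); each divergent pair contributes to a separate
undirected edge (rendered with circular ends in DOT output). Support is the
number of distinct (genome, query) witnesses, capping each genome–query
combination at one so multi-replicon records cannot double-count; graph
construction is therefore invariant to input order.

The co-occurrence statistic for a query family is the fraction of its
dereplicated neighborhoods containing at least one non-query gene whose
label is in the target set. Whether such published fractions count
neighborhoods, genomes or operons is ambiguous, so the output table reports
all three denominations; the neighborhood fraction is the primary one. No
significance test is attached: no null model for lineage sampling is
defined here.

## Synthetic pangenomes

The generator produces the survey-style input the pipeline needs, with
exact ground truth. Each genome draws its templates, lays planted operons
and unrelated background genes along a linear replicon, and derives every
planted protein from its family ancestor by substituting exactly
`round(len·(1−identity))` positions (identity drawn from a configured
range, default 0.65–0.95). Background proteins are i.i.d. uniform over the
20 residues, length uniform in [100, 300], so they are essentially never
linkable to planted families and the clustering truth is unambiguous. In
the bundled study configuration the family ancestors themselves are
rejection-sampled to be mutually non-linkable at the clustering thresholds,
since short random proteins can otherwise collide by chance.

Geometry places the two gap regimes well apart: within-operon gaps are
exponential with mean 30 bp truncated at 100 bp, while distinct
transcription units are separated by 400–1000 bp, so the 150 bp
operon-joining threshold sits safely between them. A template may plant one
extra family head-to-head with the operon's 5′ end across a 30–150 bp gap
to exercise the divergent-edge machinery. Per-genome random streams derive
from `master_seed + 1 + genome_index`, making output independent of
generation order; emitted PTT/FASTA files re-parse to the identical
in-memory tables.

Templates are organized into *groups*: a genome draws at most one template
per group, categorically by the group's prevalences. This is how a fixed
context-association fraction among query-bearing genomes is modeled — the
default study configuration plants an SRAP-like query (240 aa, the size of
that domain family) in every genome, inside a UmuD–UmuC context with
probability 0.65 and solo otherwise, and an ImuB-C-like query (80 aa) in a
DinB–LexA context with probability 0.25, mirroring the two association
levels reported for these superfamilies. What the generator does *not*
emulate: indels and alignment-length variation, compositional bias, gene
fission/fusion, paralogy within a genome, and phylogenetic correlation
between genomes. Passing recovery tests therefore demonstrates the
correctness of the bookkeeping and thresholds on well-separated families,
not robustness to real-data noise sources such as fragmented assemblies or
promiscuous multi-domain proteins.

## Conservation layer

The alignment layer consumes (never builds) protein MSAs. Per column, the
consensus category is the first match in absolute > aromatic (FYH) >
hydrophobic (ACFGHILMTVWY) > polar (CDEHKNQRST) > big (QRKEILMWYF) > none,
where a class fires when its summed residue fraction reaches the threshold
(default 0.85) and "absolute" requires a single residue in every row. The
classes overlap, so most-specific-wins ordering is pinned. Gaps count in
the consensus denominator (a half-gapped column cannot reach consensus) but
are excluded from the entropy in information content, which follows logo
convention: IC = log2(20) − H, clamped at 0, with all-gap columns reporting
0 bits. `X` matches no class and breaks absoluteness. Columns are 1-based
everywhere; `map_column_to_residue` returns the count of non-gap characters
up to and including the column, i.e. the residue number in the ungapped
row — the operation used to read catalytic-triad positions off a structure
chain included in a family alignment.

## Problem sizes and acceptance checks

The shipped checks use synthetic problem sizes chosen to exercise every
code path while keeping the suite quick: clustering oracle equivalence on
200 random instances of 3–8 sequences of 50–200 residues at five threshold
combinations; operon and divergent-pair recovery on 20 six-genome
pangenomes; co-occurrence recovery on a 200-genome pangenome (one binomial
draw, tolerance ±0.10); byte-level determinism on repeated small runs. The
acceptance script pools 24 independently seeded 100-genome pangenomes
(2400 neighborhoods per query family), bringing the binomial standard error
of the recovered association percentages to about one point.

The worked example mapping conserved SRAP columns onto PDB 1zn6 requires
the family alignment and a structure sequence, neither of which is bundled;
`scripts/structure_check.py` performs that mapping for a user-supplied
alignment (optionally verifying the reference row against RCSB over the
network).

## Known limitations

- BLASTCLUST-style clustering tools are configurable in ways that
  published analyses rarely document; the identity/coverage conventions
  here are pinned package choices, not inferred ones.
- The operon model is purely geometric (strand + distance); terminators,
  promoter motifs and expression data are out of scope.
- Origin-spanning genes on circular replicons are rejected, not split.
- Co-occurrence fractions carry no phylogenetic correction; heavily
  sampled clades inflate support counts exactly as they would have in the
  original survey, mitigated only by query-level culling.
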