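import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from genectx.simulate import (FamilyModel, OperonTemplate, PangenomeConfig)


def random_protein(rng: np.random.Generator, length: int) -> str:
    from genectx.genome import AMINO_ACIDS
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=length))


@pytest.fixture
def tiny_config() -> PangenomeConfig:
    """Three families, one 3-gene operon template plus a divergent partner."""
    rng = np.random.default_rng(99)
    families = [
        FamilyModel("QRY", random_protein(rng, 120), "query"),
        FamilyModel("CTX1", random_protein(rng, 100), "context"),
        FamilyModel("CTX2", random_protein(rng, 110), "context"),
        FamilyModel("DIV", random_protein(rng, 90), "context"),
    ]
    templates = [OperonTemplate(
        "op1", [("QRY", "+"), ("CTX1", "+"), ("CTX2", "+")], 1.0,
        divergent_partner="DIV")]
    return PangenomeConfig(families=families, templates=templates,
                           n_genomes=6, background_genes=(4, 7))


PTT_TEXT = """synthetic replicon - 1..5000
4 proteins
Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct
190..255\t+\t21\t1001\tthrA\tb0001\t-\t-\tthreonine synthase
400..900\t-\t166\t1002\t-\tb0002\t-\tCOG1\thypothetical protein
1000..1600\t+\t199\t1003\trecA\tb0003\t-\t-\trecombinase A
2000..2400\t+\t132\t1004\tlexA\tb0004\t-\t-\tSOS repressor
"""

GENBANK_TEXT = """LOCUS       TESTREP1                1200 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  synthetic test replicon.
ACCESSION   TESTREP1
VERSION     TESTREP1.1
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
FEATURES             Location/Qualifiers
     source          1..1200
     CDS             10..90
                     /gene="aaaA"
                     /protein_id="P001"
                     /product="protein A"
                     /translation="MKVLAHHEW"
     CDS             complement(100..180)
                     /protein_id="P002"
                     /product="protein B"
                     /translation="MSTVK"
     tRNA            200..275
                     /product="tRNA-Ala"
     CDS             300..380
                     /product="orphan protein"
                     /translation="MAAAW"
ORIGIN
//
"""

GENBANK_CIRCULAR_WRAP = """LOCUS       TESTCIRC                 900 bp    DNA     circular BCT 01-JAN-2000
DEFINITION  synthetic circular replicon with an origin-spanning gene.
ACCESSION   TESTCIRC
VERSION     TESTCIRC.1
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
FEATURES             Location/Qualifiers
     source          1..900
     CDS             join(800..900,1..50)
                     /protein_id="P010"
                     /product="wrapping protein"
                     /translation="MAA"
ORIGIN
//
"""


@pytest.fixture
def ptt_text() -> str:
    return PTT_TEXT


@pytest.fixture
def genbank_text() -> str:
    return GENBANK_TEXT


@pytest.fixture
def genbank_circular_wrap() -> str:
    return GENBANK_CIRCULAR_WRAP
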