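"""Shared fixtures: tiny hand-written format fixtures and random builders."""

from __future__ import annotations

import numpy as np
import pytest

from genecontext.genome_io import GeneRecord, Replicon

TOY_PTT = """Toy genome chromosome, complete genome
3 proteins
Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct
100..400\t+\t99\t1001\tabcA\tTOY_0001\t-\tCOG1\talpha protein
500..900\t+\t133\t1002\tabcB\tTOY_0002\t-\tCOG2\tbeta protein
1000..1200\t-\t66\t1003\t-\tTOY_0003\t-\t-\tgamma protein
"""

TOY_GENBANK = """\
LOCUS       TOYREP                  1300 bp    DNA     circular BCT 01-JAN-2000
DEFINITION  Toy replicon.
ACCESSION   TOYREP
VERSION     TOYREP.1
FEATURES             Location/Qualifiers
     source          1..1300
                     /organism="Toy bacterium"
     CDS             100..400
                     /locus_tag="TB_0001"
                     /product="first protein"
                     /translation="MKLVINP"
     CDS             complement(500..900)
                     /locus_tag="TB_0002"
                     /product="second protein"
                     /translation="MHEAVWK"
     CDS             join(1000..1100,1150..1250)
                     /locus_tag="TB_0003"
                     /product="joined protein"
                     /translation="MGGYQRL"
ORIGIN
//
"""

# five CA residues on a line (res 1-3 mutually close, res 4-5 far away),
# residue 2 with A/B altlocs where B has the higher occupancy
TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA AGLY A   2       3.000   0.000   0.000  0.40 10.00           C
ATOM      3  CA BGLY A   2       3.500   0.000   0.000  0.60 10.00           C
ATOM      4  CA  SER A   3       6.000   0.000   0.000  1.00 10.00           C
ATOM      5  CA  LEU A   4      40.000   0.000   0.000  1.00 10.00           C
ATOM      6  CA  VAL A   5      44.000   0.000   0.000  1.00 10.00           C
ATOM      7  N   THR A   6      50.000   0.000   0.000  1.00 10.00           N
END
"""


@pytest.fixture
def toy_ptt() -> str:
    return TOY_PTT


@pytest.fixture
def toy_genbank() -> str:
    return TOY_GENBANK


@pytest.fixture
def toy_pdb() -> str:
    return TOY_PDB


def make_replicon(
    strands: list[str],
    gaps: list[int] | None = None,
    gene_bp: int = 300,
    replicon_id: str = "rep",
    topology: str = "linear",
) -> Replicon:
    """Build a replicon from a strand pattern and intergenic gaps.

    ``gaps[i]`` is the gap preceding gene i+1 (len(strands) - 1 entries).
    """
    if gaps is None:
        gaps = [100] * (len(strands) - 1)
    assert len(gaps) == len(strands) - 1
    genes = []
    pos = 0
    for i, strand in enumerate(strands):
        start = pos + 1 if i == 0 else pos + gaps[i - 1] + 1
        end = start + gene_bp - 1
        pos = end
        genes.append(
            GeneRecord(
                gene_id=f"g{i + 1:03d}", replicon_id=replicon_id,
                genome_id="toy", start=start, end=end, strand=strand,
            )
        )
    return Replicon(replicon_id=replicon_id, genome_id="toy", genes=genes,
                    topology=topology)


def random_replicon(rng: np.random.Generator, n_genes: int) -> Replicon:
    """Random strands, gene lengths and gaps straddling the operon cutoffs."""
    strands = ["+" if b else "-" for b in rng.random(n_genes) < 0.5]
    gaps = [int(g) for g in rng.integers(0, 600, max(n_genes - 1, 0))]
    genes = []
    pos = 0
    for i, strand in enumerate(strands):
        start = pos + 1 if i == 0 else pos + gaps[i - 1] + 1
        end = start + int(rng.integers(100, 1200))
        pos = end
        genes.append(
            GeneRecord(
                gene_id=f"r{i + 1:04d}", replicon_id="rnd", genome_id="rnd",
                start=start, end=end, strand=strand,
            )
        )
    return Replicon(replicon_id="rnd", genome_id="rnd", genes=genes)
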