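"""Readers/writers for gene-coordinate tables and the in-memory genome model.

The pipeline walks ordered, stranded gene lists per replicon.  Coordinates
are 1-based inclusive (the PTT/GenBank convention); gene order is expressed
as a 0-based ``rank`` assigned after sorting by start position.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class GeneTableError(ValueError):
    """Malformed or inconsistent gene-table input."""


@dataclass
class GeneRecord:
    """A single protein-coding gene on a replicon.

    ``start``/``end`` are 1-based inclusive base-pair positions with
    ``start <= end`` regardless of strand; ``rank`` is the 0-based index in
    the replicon's start-sorted gene order.
    """

    gene_id: str
    replicon_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    rank: int = -1
    product: str = ""
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GeneTableError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GeneTableError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.protein_seq is not None:
            bad = set(self.protein_seq) - VALID_AA
            if bad:
                raise GeneTableError(
                    f"gene {self.gene_id}: illegal residues {sorted(bad)}"
                )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class Replicon:
    """An ordered list of genes on one chromosome or plasmid."""

    replicon_id: str
    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    topology: str = "linear"  # or "circular"
    synthetic_coordinates: bool = False

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise GeneTableError(f"unknown topology {self.topology!r}")
        self.sort_and_rank()

    def sort_and_rank(self) -> None:
        """Sort genes by (start, end, gene_id) and assign consecutive ranks."""
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        seen: set[str] = set()
        for i, g in enumerate(self.genes):
            if g.gene_id in seen:
                raise GeneTableError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            g.rank = i

    def gene_by_id(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"gene {gene_id!r} not in replicon {self.replicon_id!r}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Genome:
    genome_id: str
    clade: str = ""
    replicons: list[Replicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.replicon_id for r in self.replicons]
        if len(ids) != len(set(ids)):
            raise GeneTableError(
                f"genome {self.genome_id}: duplicate replicon ids"
            )

    def all_genes(self) -> Iterable[GeneRecord]:
        for rep in self.replicons:
            yield from rep.genes


_LOCATION_RE = re.compile(r"^(\d+)\.\.(\d+)$")


def read_ptt(stream: IO[str], genome_id: str, replicon_id: str) -> Replicon:
    """Parse an NCBI PTT-dialect protein table into a :class:`Replicon`.

    PTT files carry two free-text header lines, then a column-header line,
    then tab-separated rows ``Location  Strand  Length  PID  Gene  Synonym
    Code  COG  Product``.  The Synonym column supplies the locus tag used
    as ``gene_id``; rows may appear in any order.
    """
    lines = stream.read().splitlines()
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    in_data = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not in_data:
            # data starts after the column-header line (begins with "Location")
            if line.split("\t")[0].strip().lower() == "location":
                in_data = True
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise GeneTableError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
            )
        m = _LOCATION_RE.match(fields[0].strip())
        if not m:
            raise GeneTableError(
                f"line {lineno}: malformed Location field {fields[0]!r}"
            )
        start, end = int(m.group(1)), int(m.group(2))
        strand = fields[1].strip()
        synonym = fields[5].strip()
        if synonym in seen:
            raise GeneTableError(f"line {lineno}: duplicate Synonym {synonym!r}")
        seen.add(synonym)
        genes.append(
            GeneRecord(
                gene_id=synonym,
                replicon_id=replicon_id,
                genome_id=genome_id,
                start=start,
                end=end,
                strand=strand,
                product=fields[8].strip(),
            )
        )
    return Replicon(replicon_id=replicon_id, genome_id=genome_id, genes=genes)


def write_ptt(replicon: Replicon, stream: IO[str]) -> None:
    """Write a replicon back out in the PTT dialect `read_ptt` accepts."""
    stream.write(f"{replicon.genome_id} {replicon.replicon_id}\n")
    stream.write(f"{len(replicon.genes)} proteins\n")
    stream.write(
        "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n"
    )
    for g in replicon.genes:
        aalen = max(g.length_bp // 3 - 1, 1)
        stream.write(
            f"{g.start}..{g.end}\t{g.strand}\t{aalen}\t-\t-\t{g.gene_id}\t-\t-\t{g.product}\n"
        )


def read_genbank_features(stream: IO[str]) -> list[Replicon]:
    """Extract CDS features from GenBank flat-file records.

    Each record becomes one replicon; ``complement(..)`` locations map to
    the minus strand and compound ``join(..)`` locations collapse to their
    outermost span (the neighborhood logic only needs order and strand).
    CDS features lacking a locus_tag get a synthesized id.
    """
    replicons: list[Replicon] = []
    for rec in SeqIO.parse(stream, "genbank"):
        topology = rec.annotations.get("topology", "linear")
        if topology not in ("linear", "circular"):
            topology = "linear"
        genes: list[GeneRecord] = []
        n_anon = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            tags = quals.get("locus_tag")
            if tags:
                gene_id = tags[0]
            else:
                n_anon += 1
                gene_id = f"{rec.id}_cds{n_anon}"
                logger.warning(
                    "CDS at %s lacks locus_tag; synthesized id %s",
                    feat.location, gene_id,
                )
            if len(feat.location.parts) > 1:
                logger.warning(
                    "CDS %s has a compound location; using outermost span",
                    gene_id,
                )
            start = int(feat.location.start) + 1  # Biopython is 0-based
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            translation = quals.get("translation", [None])[0]
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    replicon_id=rec.id,
                    genome_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=quals.get("product", [""])[0],
                    protein_seq=translation,
                )
            )
        replicons.append(
            Replicon(
                replicon_id=rec.id,
                genome_id=rec.id,
                genes=genes,
                topology=topology,
            )
        )
    return replicons


GENE_TABLE_COLUMNS = ["gene_id", "replicon_id", "start", "end", "strand", "rank", "product"]


def write_gene_table(replicon: Replicon, stream: IO[str]) -> None:
    """Write the canonical TSV gene table, one row per gene in rank order."""
    stream.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
    for g in replicon.genes:
        stream.write(
            f"{g.gene_id}\t{g.replicon_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.rank}\t{g.product}\n"
        )


def read_gene_table(stream: IO[str], genome_id: str = "") -> Replicon:
    """Read the TSV written by :func:`write_gene_table`."""
    lines = [ln for ln in stream.read().splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header != GENE_TABLE_COLUMNS:
        raise GeneTableError(f"unexpected gene-table header {header}")
    genes = []
    replicon_id = ""
    for ln in lines[1:]:
        f = ln.split("\t")
        replicon_id = f[1]
        genes.append(
            GeneRecord(
                gene_id=f[0], replicon_id=f[1], genome_id=genome_id,
                start=int(f[2]), end=int(f[3]), strand=f[4],
                product=f[6] if len(f) > 6 else "",
            )
        )
    return Replicon(replicon_id=replicon_id or "replicon", genome_id=genome_id, genes=genes)


def write_fasta(seqs: dict[str, str], stream: IO[str]) -> None:
    for sid in sorted(seqs):
        stream.write(f">{sid}\n{seqs[sid]}\n")


def read_fasta(stream: IO[str]) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(stream, "fasta")}


# The 13-gene neighborhood of the CA_C2195 anchor in Clostridium
# acetobutylicum, as printed in the source study's gene-neighborhood table.
# No coordinates are printed there, so the fixture synthesizes consecutive
# same-strand coordinates (900 bp genes, 100 bp gaps) and flags them as such.
_TABLE2_ROWS: list[tuple[str, str, str]] = [
    ("CA_C2186", ".", "Glycosyltransferase"),
    ("CA_C2187", "spsE",
     "N-acetylneuraminic acid synthase + SAF sugar-binding "
     "(condenses of phosphoenolpyruvate and N-acetylmannosamine)"),
    ("CA_C2188", ".", "Glycosyltransferase"),
    ("CA_C2189", ".", "ATP-grasp amino acyl ligase"),
    ("CA_C2190", "spsF", "Sugar phosphate nucleotidyltransferase"),
    ("CA_C2192", ".", "Glyoxylase"),
    ("CA_C2193", ".", "DUF3880 + Glycosyltransferase"),
    ("CA_C2194", ".", "nucleoside-diphosphate sugar epimerase"),
    ("CA_C2195", ".", "Peptidase-like (peptidase_MH superfamily)"),
    ("CA_C2196", ".",
     "Methyltransferase + Glycosyltransferase "
     "(currently annotated as: MAF_flag10, DUF115)"),
    ("CA_C2197", ".", "aminosugar N-acetyltransferase"),
    ("CA_C2198", "acpA", "acyl carrier protein"),
    ("CA_C2199", ".", "aminosugsar N-acetyltransferase + HAD Phosphatase"),
]

TABLE2_ANCHOR_ID = "CA_C2195"


def fixture_table2() -> Replicon:
    """The published CA_C2195 neighborhood as a ready-made replicon.

    Returns the 13 printed loci (CA_C2186..CA_C2199, CA_C2191 absent from
    the published table) with synthesized coordinates: all on the plus
    strand, 900 bp genes separated by 100 bp gaps.
    ``Replicon.synthetic_coordinates`` is True to flag that geometry as
    invented.
    """
    genes = []
    for i, (locus, _name, product) in enumerate(_TABLE2_ROWS):
        start = 1 + i * 1000
        genes.append(
            GeneRecord(
                gene_id=locus,
                replicon_id="CAC_chromosome",
                genome_id="Clostridium_acetobutylicum",
                start=start,
                end=start + 899,
                strand="+",
                product=product,
            )
        )
    return Replicon(
        replicon_id="CAC_chromosome",
        genome_id="Clostridium_acetobutylicum",
        genes=genes,
        synthetic_coordinates=True,
    )
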