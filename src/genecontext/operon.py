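"""Operon calling by strand runs and intergenic gaps.

Genes are merged into one putative operon when they are rank-adjacent, on
the same strand, and separated by at most ``max_gap`` base pairs — the gap
threshold is the proxy for "sharing a promoter", since co-transcribed
bacterial genes rarely leave long intergenic stretches.  Adjacent
head-to-head (−,+) pairs with a short gap are reported separately as
candidate bidirectional-promoter pairs; they are never merged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import Replicon
from .neighborhood import Neighborhood

DEFAULT_OPERON_GAP = 200
DEFAULT_DIVERGENT_GAP = 300


@dataclass
class Operon:
    operon_id: str
    gene_ids: list[str]
    strand: str
    replicon_id: str

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class DivergentPair:
    left_gene_id: str
    right_gene_id: str
    intergenic_gap: int


@dataclass
class AnchorOperonContext:
    """Where the anchor sits inside its operon."""

    operon_id: str
    n_coperonic_5prime: int
    n_coperonic_3prime: int

    @property
    def embedded(self) -> bool:
        """True when co-operonic genes flank the anchor on both sides."""
        return self.n_coperonic_5prime >= 1 and self.n_coperonic_3prime >= 1


def intergenic_gap(prev_end: int, next_start: int) -> int:
    """Base pairs between two rank-adjacent genes, floored at 0 for overlaps."""
    return max(next_start - prev_end - 1, 0)


def call_operons(replicon: Replicon, max_gap: int = DEFAULT_OPERON_GAP) -> list[Operon]:
    """Partition a replicon's genes into putative operons.

    Returns maximal runs of rank-adjacent same-strand genes whose pairwise
    intergenic gaps are all <= ``max_gap``; every gene lands in exactly one
    operon and singletons are allowed.
    """
    operons: list[Operon] = []
    current: list = []
    for gene in replicon.genes:
        if current:
            prev = current[-1]
            if gene.strand == prev.strand and intergenic_gap(prev.end, gene.start) <= max_gap:
                current.append(gene)
                continue
            operons.append(_finish(current, replicon, len(operons)))
            current = []
        current.append(gene)
    if current:
        operons.append(_finish(current, replicon, len(operons)))
    return operons


def _finish(genes: list, replicon: Replicon, index: int) -> Operon:
    return Operon(
        operon_id=f"{replicon.replicon_id}_op{index + 1:04d}",
        gene_ids=[g.gene_id for g in genes],
        strand=genes[0].strand,
        replicon_id=replicon.replicon_id,
    )


def find_divergent_pairs(
    replicon: Replicon, max_gap: int = DEFAULT_DIVERGENT_GAP
) -> list[DivergentPair]:
    """Adjacent head-to-head (−, then +) gene pairs with gap <= max_gap."""
    pairs = []
    for prev, nxt in zip(replicon.genes, replicon.genes[1:]):
        if prev.strand == "-" and nxt.strand == "+":
            gap = intergenic_gap(prev.end, nxt.start)
            if gap <= max_gap:
                pairs.append(
                    DivergentPair(
                        left_gene_id=prev.gene_id,
                        right_gene_id=nxt.gene_id,
                        intergenic_gap=gap,
                    )
                )
    return pairs


def gene_to_operon(operons: list[Operon]) -> dict[str, str]:
    return {g: op.operon_id for op in operons for g in op.gene_ids}


def anchor_operon_context(
    neighborhood: Neighborhood, operons: list[Operon]
) -> AnchorOperonContext:
    """Count co-operonic neighbors on each side of a neighborhood's anchor."""
    lookup = gene_to_operon(operons)
    anchor_id = neighborhood.anchor.gene_id
    if anchor_id not in lookup:
        raise ValueError(f"anchor {anchor_id!r} not covered by the operon list")
    op = lookup[anchor_id]
    n5 = sum(1 for g in neighborhood.neighbors_5prime if lookup.get(g.gene_id) == op)
    n3 = sum(1 for g in neighborhood.neighbors_3prime if lookup.get(g.gene_id) == op)
    return AnchorOperonContext(operon_id=op, n_coperonic_5prime=n5, n_coperonic_3prime=n3)
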