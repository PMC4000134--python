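"""Anchor location and rank-window neighborhood extraction.

A neighborhood is the anchor gene plus up to ``window`` genes on each side,
measured in gene ranks (not base pairs).  By default the 5' side is the
lower-rank side in replicon coordinates; ``orient_by_strand=True`` flips the
sides for minus-strand anchors so that 5'/3' follow the anchor's reading
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome_io import GeneRecord, Genome, Replicon

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 20


@dataclass
class AnchorSet:
    family_label: str
    members: list[tuple[str, str]] = field(default_factory=list)  # (genome_id, gene_id)


@dataclass
class Neighborhood:
    anchor: GeneRecord
    neighbors_5prime: list[GeneRecord]  # nearest first
    neighbors_3prime: list[GeneRecord]  # nearest first
    window: int

    @property
    def genome_id(self) -> str:
        return self.anchor.genome_id

    def all_genes(self) -> list[GeneRecord]:
        """Anchor plus both sides, in replicon order when un-reoriented."""
        return list(reversed(self.neighbors_5prime)) + [self.anchor] + self.neighbors_3prime

    def __len__(self) -> int:
        return 1 + len(self.neighbors_5prime) + len(self.neighbors_3prime)


def find_anchors(
    genomes: list[Genome],
    membership: dict[str, str],
    family_label: str,
) -> AnchorSet:
    """Collect all genes assigned to ``family_label`` across genomes.

    ``membership`` maps gene_id -> family label (from clustering or from a
    supplied domain table).  Returns members in deterministic
    (genome_id, gene_id) order; an absent label yields an empty set with a
    logged warning.
    """
    if family_label not in set(membership.values()):
        logger.warning("family label %r not present in membership", family_label)
        return AnchorSet(family_label=family_label)
    members = []
    for genome in genomes:
        for gene in genome.all_genes():
            if membership.get(gene.gene_id) == family_label:
                members.append((genome.genome_id, gene.gene_id))
    members.sort()
    return AnchorSet(family_label=family_label, members=members)


def extract_neighborhood(
    replicon: Replicon,
    anchor_id: str,
    window: int = DEFAULT_WINDOW,
    orient_by_strand: bool = False,
) -> Neighborhood:
    """Take up to ``window`` genes on each side of the anchor by rank.

    Linear replicons truncate silently at their ends; circular replicons
    wrap, capping the total gene count at the replicon size (no gene is
    reported twice).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    anchor = replicon.gene_by_id(anchor_id)
    n = len(replicon.genes)
    a = anchor.rank

    lo_side: list[GeneRecord] = []  # decreasing rank, nearest first
    hi_side: list[GeneRecord] = []  # increasing rank, nearest first
    if replicon.topology == "circular":
        used = {a}
        for d in range(1, window + 1):
            r = (a - d) % n
            if r in used:
                break
            used.add(r)
            lo_side.append(replicon.genes[r])
        for d in range(1, window + 1):
            r = (a + d) % n
            if r in used:
                break
            used.add(r)
            hi_side.append(replicon.genes[r])
    else:
        lo_side = [replicon.genes[r] for r in range(a - 1, max(a - window, 0) - 1, -1)]
        hi_side = [replicon.genes[r] for r in range(a + 1, min(a + window, n - 1) + 1)]

    if orient_by_strand and anchor.strand == "-":
        lo_side, hi_side = hi_side, lo_side
    return Neighborhood(
        anchor=anchor,
        neighbors_5prime=lo_side,
        neighbors_3prime=hi_side,
        window=window,
    )
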