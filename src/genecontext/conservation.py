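"""Alignment-column conservation, 1-9 grading, and structure mapping.

The conservation score is a sequence-weighted relative entropy of each
column's residue frequencies against a fixed background amino-acid
composition; position-based (Henikoff-Henikoff) weights damp redundant
sequences.  Scores are binned into nine grades (9 = most conserved, the
convention of structure-markup conservation servers), grades are projected
through the alignment's reference sequence onto residue numbers, and
highly conserved residues are clustered in 3D by single-linkage under a
distance cutoff — the route from an alignment to a putative active-site
patch on a structure.

Bayesian rate inference over a phylogeny (as conservation servers run
internally) is deliberately not reproduced; the weighted relative entropy
keeps the same decision structure (scores -> 1-9 grades -> structure) with
transparent, dependency-light math.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Optional

import gemmi
import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MAX_GAP_FRACTION = 0.5
MIN_SEQUENCES = 5

# Robinson & Robinson amino-acid background composition (normalised)
DEFAULT_BACKGROUND = {
    "A": 0.0780, "C": 0.0193, "D": 0.0538, "E": 0.0632, "F": 0.0396,
    "G": 0.0738, "H": 0.0219, "I": 0.0514, "K": 0.0574, "L": 0.0901,
    "M": 0.0224, "N": 0.0448, "P": 0.0520, "Q": 0.0426, "R": 0.0512,
    "S": 0.0712, "T": 0.0584, "V": 0.0644, "W": 0.0132, "Y": 0.0321,
}


@dataclass
class Alignment:
    """A multiple sequence alignment with a designated reference row."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.reference_id not in self.ids:
            raise ValueError(
                f"reference {self.reference_id!r} not among ids; "
                f"valid ids include {self.ids[:5]}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]


def read_alignment(stream: IO[str], reference_id: str, fmt: str = "fasta") -> Alignment:
    """Load a FASTA or Stockholm alignment via Biopython."""
    msa = AlignIO.read(stream, fmt)
    return Alignment(
        ids=[rec.id for rec in msa],
        rows=[str(rec.seq).upper().replace(".", GAP) for rec in msa],
        reference_id=reference_id,
    )


@dataclass
class ConservationProfile:
    column_scores: np.ndarray            # NaN where ungraded
    grades: list[Optional[int]] = field(default_factory=list)
    ref_map: dict[int, int] = field(default_factory=dict)  # column -> residue number
    invariant_columns: list[int] = field(default_factory=list)


def henikoff_weights(rows: list[str]) -> np.ndarray:
    """Position-based sequence weights, normalised to sum to 1.

    At each column a sequence receives 1/(r * s) where r is the number of
    distinct symbols in the column and s the count of the sequence's own
    symbol; gaps count as a symbol class.  Duplicating the whole sequence
    set rescales all weights equally, leaving weighted frequencies intact.
    """
    n = len(rows)
    weights = np.zeros(n)
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for i, c in enumerate(col):
            weights[i] += 1.0 / (r * counts[c])
    total = weights.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return weights / total


def compute_conservation(
    aln: Alignment,
    background: Optional[dict[str, float]] = None,
) -> ConservationProfile:
    """Score every column by weighted relative entropy against background.

    Columns with more than 50% gaps get NaN (they stay ungraded).  Scores
    are nonnegative; an invariant column scores highest within its
    alignment, a maximally diverse column lowest.
    """
    if aln.n_sequences < MIN_SEQUENCES:
        raise ValueError(
            f"conservation needs >= {MIN_SEQUENCES} sequences for a usable "
            f"profile; got {aln.n_sequences} (add homologs or lower stringency "
            "is not supported)"
        )
    bg = background or DEFAULT_BACKGROUND
    q = np.array([bg[a] for a in AMINO_ACIDS])
    q = q / q.sum()
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    weights = henikoff_weights(aln.rows)
    ncol = aln.n_columns
    scores = np.full(ncol, np.nan)
    invariant: list[int] = []
    cols = list(zip(*aln.rows))
    for j in range(ncol):
        col = cols[j]
        gap_frac = sum(1 for c in col if c not in aa_index) / len(col)
        if gap_frac > MAX_GAP_FRACTION:
            continue
        freq = np.zeros(len(AMINO_ACIDS))
        for c, w in zip(col, weights):
            if c in aa_index:
                freq[aa_index[c]] += w
        total = freq.sum()
        if total <= 0:
            continue
        freq /= total
        nz = freq > 0
        scores[j] = float(np.sum(freq[nz] * np.log2(freq[nz] / q[nz])))
        residues = {c for c in col if c in aa_index}
        if len(residues) == 1:
            invariant.append(j)
    return ConservationProfile(column_scores=scores, invariant_columns=invariant)


def bin_grades(profile: ConservationProfile) -> ConservationProfile:
    """Fill 1-9 conservation grades from the scores (9 = top ninth).

    Scored columns are cut at the 1/9..8/9 score quantiles; equal scores
    always receive equal grades and grades never decrease with score.
    Invariant columns are forced to grade 9 regardless of quantile edges.
    With fewer than nine scored columns, grades spread the score ranks
    evenly over 1..9 instead (a single scored column grades 9).
    """
    scores = profile.column_scores
    scored = ~np.isnan(scores)
    vals = scores[scored]
    grades: list[Optional[int]] = [None] * len(scores)
    if vals.size:
        if vals.size >= 9:
            edges = np.quantile(vals, np.arange(1, 9) / 9.0)
            binned = 1 + np.searchsorted(edges, vals, side="right")
        else:
            uniq = np.unique(vals)
            if uniq.size == 1:
                binned = np.full(vals.size, 9)
            else:
                rank = np.searchsorted(uniq, vals)
                binned = 1 + np.floor(rank / (uniq.size - 1) * 8).astype(int)
        idx = np.flatnonzero(scored)
        for j, g in zip(idx, binned):
            grades[j] = int(g)
    for j in profile.invariant_columns:
        if grades[j] is not None:
            grades[j] = 9
    profile.grades = grades
    return profile


def map_to_reference(
    profile: ConservationProfile, aln: Alignment, offset: int = 0
) -> dict[int, Optional[int]]:
    """Project per-column grades onto reference residue numbers.

    Reference residues are numbered 1..L over the ungapped reference row
    (plus ``offset`` for constructs whose coordinate numbering differs);
    alignment columns where the reference is gapped are dropped.  Also
    fills ``profile.ref_map`` (column -> residue number).
    """
    ref = aln.reference_row()
    residue_grades: dict[int, Optional[int]] = {}
    ref_map: dict[int, int] = {}
    resnum = 0
    for col, c in enumerate(ref):
        if c == GAP:
            continue
        resnum += 1
        number = resnum + offset
        ref_map[col] = number
        residue_grades[number] = (
            profile.grades[col] if col < len(profile.grades or []) else None
        )
    profile.ref_map = ref_map
    return residue_grades


@dataclass
class ResidueCoordinates:
    chain_id: str
    positions: dict[int, np.ndarray]  # residue number -> xyz (Angstrom)

    def __len__(self) -> int:
        return len(self.positions)


def read_structure_coords(
    pdb_text: str, chain: str, atom: str = "CA"
) -> ResidueCoordinates:
    """One representative-atom coordinate per residue from PDB ATOM records.

    Alternate locations resolve to the highest-occupancy conformer (ties to
    the lowest altloc id); residues lacking the requested atom are skipped
    with a warning.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("no models in PDB input")
    model = structure[0]
    chain_obj = model.find_chain(chain)
    if chain_obj is None:
        available = [ch.name for ch in model]
        raise KeyError(f"chain {chain!r} not found; available: {available}")
    positions: dict[int, np.ndarray] = {}
    for residue in chain_obj:
        if residue.het_flag != "A":  # ATOM records only
            continue
        candidates = [a for a in residue if a.name == atom]
        if not candidates:
            logger.warning(
                "residue %s %d lacks atom %s; skipped",
                residue.name, residue.seqid.num, atom,
            )
            continue
        best = min(candidates, key=lambda a: (-a.occ, a.altloc))
        positions[residue.seqid.num] = np.array(
            [best.pos.x, best.pos.y, best.pos.z]
        )
    return ResidueCoordinates(chain_id=chain, positions=positions)


@dataclass
class ConservedCluster:
    residue_numbers: list[int]
    min_grade: int
    diameter: float

    def __len__(self) -> int:
        return len(self.residue_numbers)


def conserved_spatial_cluster(
    grades: dict[int, Optional[int]],
    coords: ResidueCoordinates,
    min_grade: int = 9,
    cutoff: float = 8.0,
) -> list[ConservedCluster]:
    """Spatial single-linkage clusters of highly conserved residues.

    Takes residues with grade >= min_grade that have coordinates, links
    pairs within ``cutoff`` Angstrom, and returns the connected components
    sorted by size descending (ties by smallest residue number).
    """
    members = sorted(
        r for r, g in grades.items()
        if g is not None and g >= min_grade and r in coords.positions
    )
    if not members:
        return []
    pts = np.array([coords.positions[r] for r in members])
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    adj = dist <= cutoff

    seen: set[int] = set()
    clusters = []
    for i in range(len(members)):
        if i in seen:
            continue
        stack, comp = [i], []
        seen.add(i)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adj[u]):
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        comp.sort()
        diameter = float(dist[np.ix_(comp, comp)].max()) if len(comp) > 1 else 0.0
        clusters.append(
            ConservedCluster(
                residue_numbers=[members[u] for u in comp],
                min_grade=min_grade,
                diameter=diameter,
            )
        )
    clusters.sort(key=lambda c: (-len(c.residue_numbers), c.residue_numbers[0]))
    return clusters
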