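"""Synthetic genomes and alignments with machine-readable ground truth.

The genome simulator emulates the corpus behind an anchor-centred
gene-neighborhood study: bacterial genomes of ~4000 protein-coding genes,
each carrying one anchor-family gene, with a set of linked sugar-enzyme
families planted within a +/-20-gene window of the anchor in a subset of
genomes that spans several clades, plus occasional decoy families placed
anywhere.  Family member proteins are point-mutated copies of a per-family
template, so homology clustering has a real (non-tautological) recovery
job; background proteins are random.

The alignment simulator emulates a homolog alignment in a chosen pairwise
identity band with planted invariant columns.

Everything is deterministic given the seed, and every planted fact is
returned in a truth object that tests read instead of re-deriving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conservation import AMINO_ACIDS, Alignment
from .genome_io import GeneRecord, Genome, Replicon, write_fasta, write_ptt

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

ANCHOR_FAMILY = "DUF4910 peptidase-like"

# the five linked sugar-modification enzyme families of the motivating study
DEFAULT_PLANTED_FAMILIES = [
    "NDP-sugar epimerase/dehydratase",
    "Sugar phosphate nucleotidyltransferase",
    "Glycosyltransferase",
    "Aminosugar N-acetyltransferase",
    "SAM-dependent sugar methylase",
]

DEFAULT_CLADES = [
    "actinobacteria", "firmicutes", "cyanobacteria", "planctomycetes",
    "bacteroidetes", "nitrospirae", "alphaproteobacteria",
    "betaproteobacteria", "epsilonproteobacteria", "spirochaetes",
]

DECOY_FAMILIES = ["Decoy transposase", "Decoy ABC transporter", "Decoy kinase"]

_BACKGROUND_PRODUCTS = [
    "hypothetical protein", "membrane protein", "ABC transporter permease",
    "transcriptional regulator", "ribosomal protein", "dehydrogenase",
]


@dataclass
class GenomeSimParams:
    n_genomes: int = 20
    genes_per_genome: int = 4000
    clade_labels: list[str] = field(default_factory=lambda: list(DEFAULT_CLADES))
    planted_families: list[str] = field(
        default_factory=lambda: list(DEFAULT_PLANTED_FAMILIES)
    )
    presence_prob: float = 0.9
    window_jitter: int = 20
    same_operon_prob: float = 0.75
    decoy_rate: float = 0.5
    mutation_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.presence_prob, self.same_operon_prob, self.mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not 1 <= self.window_jitter <= 20:
            raise ValueError("window_jitter must be in 1..20")
        if self.genes_per_genome <= 2 * self.window_jitter + 1:
            raise ValueError("genes_per_genome too small for the jitter window")
        if len(self.planted_families) > 2 * self.window_jitter:
            raise ValueError("more planted families than window slots")


@dataclass
class SimTruth:
    """What the generator actually planted, keyed for direct lookup."""

    per_genome: dict[str, dict] = field(default_factory=dict)
    per_family: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"per_genome": self.per_genome, "per_family": self.per_family},
            indent=1, sort_keys=True,
        )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return _AA_BYTES[rng.integers(0, 20, length)].tobytes().decode()


def _mutate(rng: np.random.Generator, template: str, rate: float) -> str:
    """Point-substitute each position with probability ``rate``."""
    arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        # shift by 1..19 in the 20-letter index space: always a different aa
        idx = np.searchsorted(_AA_BYTES, arr[hit])
        arr[hit] = _AA_BYTES[(idx + rng.integers(1, 20, hit.size)) % 20]
    return arr.tobytes().decode()


def simulate_genomes(params: GenomeSimParams) -> tuple[list[Genome], SimTruth]:
    """Generate genomes with planted anchor neighborhoods plus truth.

    Every genome gets one anchor gene; a genome "carries" the planted
    neighborhood with probability ``presence_prob``, in which case each
    planted family contributes one gene at a distinct rank offset within
    +/-``window_jitter`` of the anchor.  With probability
    ``same_operon_prob`` the planted span is forced onto the anchor strand
    with short intergenic gaps (a co-operonic neighborhood); otherwise
    strands and gaps stay background-random.  Decoy-family genes land at
    uniform ranks at ``decoy_rate`` expected occurrences per genome.
    """
    rng = np.random.default_rng(params.seed)
    templates = {
        ANCHOR_FAMILY: _random_protein(rng, 140),
        **{fam: _random_protein(rng, 100 + 8 * i)
           for i, fam in enumerate(params.planted_families)},
        **{fam: _random_protein(rng, 90 + 10 * i)
           for i, fam in enumerate(DECOY_FAMILIES)},
    }

    genomes: list[Genome] = []
    truth = SimTruth(per_family={fam: [] for fam in params.planted_families})
    n = params.genes_per_genome
    jit = params.window_jitter

    for gi in range(params.n_genomes):
        genome_id = f"G{gi + 1:03d}"
        clade = params.clade_labels[gi % len(params.clade_labels)]

        anchor_rank = int(rng.integers(jit, n - jit))
        carrier = bool(rng.random() < params.presence_prob)
        planted_at: dict[int, str] = {}
        if carrier:
            offsets = np.concatenate([np.arange(-jit, 0), np.arange(1, jit + 1)])
            chosen = rng.choice(offsets, size=len(params.planted_families),
                                replace=False)
            for fam, off in zip(params.planted_families, chosen):
                planted_at[anchor_rank + int(off)] = fam

        n_decoys = int(rng.poisson(params.decoy_rate))
        decoy_at: dict[int, str] = {}
        taken = set(planted_at) | {anchor_rank}
        for _ in range(n_decoys):
            while True:
                r = int(rng.integers(0, n))
                if r not in taken:
                    break
            taken.add(r)
            decoy_at[r] = DECOY_FAMILIES[int(rng.integers(0, len(DECOY_FAMILIES)))]

        strands = np.where(rng.random(n) < 0.5, "+", "-")
        gene_bp = rng.integers(300, 1500, n)
        gaps = rng.integers(20, 351, n)  # gap[i] precedes gene i

        co_operonic = False
        if carrier and planted_at and rng.random() < params.same_operon_prob:
            co_operonic = True
            lo = min(min(planted_at), anchor_rank)
            hi = max(max(planted_at), anchor_rank)
            strands[lo : hi + 1] = strands[anchor_rank]
            gaps[lo + 1 : hi + 1] = rng.integers(20, 120, hi - lo)

        bg_len = rng.integers(60, 141, n)
        bg_products = rng.integers(0, len(_BACKGROUND_PRODUCTS), n)

        genes: list[GeneRecord] = []
        pos = 0
        planted_ids: dict[str, str] = {}
        anchor_id = ""
        for r in range(n):
            pos += int(gaps[r])
            start = pos + 1
            end = pos + int(gene_bp[r])
            pos = end
            gene_id = f"{genome_id}_g{r + 1:05d}"
            if r == anchor_rank:
                fam = ANCHOR_FAMILY
                anchor_id = gene_id
            elif r in planted_at:
                fam = planted_at[r]
                planted_ids[fam] = gene_id
            elif r in decoy_at:
                fam = decoy_at[r]
            else:
                fam = None
            if fam is None:
                seq = _random_protein(rng, int(bg_len[r]))
                product = _BACKGROUND_PRODUCTS[int(bg_products[r])]
            else:
                seq = _mutate(rng, templates[fam], params.mutation_rate)
                product = fam
            genes.append(
                GeneRecord(
                    gene_id=gene_id, replicon_id=f"{genome_id}_chr",
                    genome_id=genome_id, start=start, end=end,
                    strand=str(strands[r]), product=product, protein_seq=seq,
                )
            )
        replicon = Replicon(
            replicon_id=f"{genome_id}_chr", genome_id=genome_id, genes=genes
        )
        genomes.append(Genome(genome_id=genome_id, clade=clade, replicons=[replicon]))

        truth.per_genome[genome_id] = {
            "anchor": anchor_id,
            "clade": clade,
            "carrier": carrier,
            "co_operonic": co_operonic,
            "planted": planted_ids,
            "decoys": {
                f"{genome_id}_g{r + 1:05d}": fam for r, fam in sorted(decoy_at.items())
            },
        }
        for fam in planted_ids:
            truth.per_family[fam].append(genome_id)
    return genomes, truth


def domain_table(genomes: list[Genome], truth: SimTruth) -> dict[str, str]:
    """The protein -> domain-architecture table implied by the truth.

    Covers anchor, planted-family and decoy genes; background genes are
    deliberately absent (no domain hit), exercising majority labelling.
    """
    table: dict[str, str] = {}
    for genome_id, info in truth.per_genome.items():
        table[info["anchor"]] = ANCHOR_FAMILY
        for fam, gene_id in info["planted"].items():
            table[gene_id] = fam
        for gene_id, fam in info["decoys"].items():
            table[gene_id] = fam
    return table


def clade_map(genomes: list[Genome]) -> dict[str, str]:
    return {g.genome_id: g.clade for g in genomes}


def protein_map(genomes: list[Genome]) -> dict[str, str]:
    return {g.gene_id: g.protein_seq for gm in genomes for g in gm.all_genes()}


@dataclass
class AlignmentSimParams:
    n_sequences: int = 30
    n_columns: int = 100
    invariant_columns: list[int] = field(default_factory=lambda: list(range(10)))
    identity_band: tuple[float, float] = (0.35, 0.80)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= c < self.n_columns for c in self.invariant_columns):
            raise ValueError("invariant_columns out of range")
        lo, hi = self.identity_band
        if not (0.0 < lo <= hi < 1.0 or (lo == hi == 1.0)):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError("identity band must lie in (0, 1]")


def _dominance_for_identity(match_prob: float) -> float:
    """Dominant-residue probability c with c^2 + (1-c)^2/19 = match_prob."""
    if not (1.0 / 20.0 <= match_prob <= 1.0):
        raise ValueError(
            f"per-column match probability {match_prob:.3f} unattainable "
            "with a 20-letter alphabet (needs 0.05..1)"
        )
    # (20/19) c^2 - (2/19) c + (1/19 - m) = 0
    a, b, cc = 20.0 / 19.0, -2.0 / 19.0, 1.0 / 19.0 - match_prob
    disc = b * b - 4 * a * cc
    return float((-b + np.sqrt(disc)) / (2 * a))


def simulate_alignment(params: AlignmentSimParams) -> tuple[Alignment, dict]:
    """Generate a gap-free homolog alignment with planted invariant columns.

    Variable columns draw from a column-specific distribution with one
    dominant residue whose weight is tuned so the expected mean pairwise
    identity hits the middle of ``identity_band``; a variable column that
    comes out accidentally invariant is re-touched so the emitted invariant
    set equals the planted one exactly.  Truth returns the planted columns
    and the tuned parameters.
    """
    rng = np.random.default_rng(params.seed)
    ncol, nseq = params.n_columns, params.n_sequences
    inv = sorted(set(params.invariant_columns))
    f_inv = len(inv) / ncol
    target = sum(params.identity_band) / 2.0

    mat = np.empty((nseq, ncol), dtype=np.uint8)
    if len(inv) < ncol:
        m = (target - f_inv) / (1.0 - f_inv)
        c = _dominance_for_identity(m)
        dominant = rng.integers(0, 20, ncol)
        others = rng.integers(0, 19, (nseq, ncol))
        # map 0..18 onto the 19 non-dominant letters
        alt = others + (others >= dominant[None, :])
        use_dom = rng.random((nseq, ncol)) < c
        mat = np.where(use_dom, dominant[None, :], alt).astype(np.uint8)
        # re-touch accidentally invariant variable columns
        inv_set = set(inv)
        for j in range(ncol):
            if j in inv_set:
                continue
            if len(np.unique(mat[:, j])) == 1:
                i = int(rng.integers(0, nseq))
                mat[i, j] = (mat[i, j] + 1 + rng.integers(0, 19)) % 20
    else:
        c = 1.0
    inv_residues = rng.integers(0, 20, len(inv))
    for j, res in zip(inv, inv_residues):
        mat[:, j] = res

    rows = [_AA_BYTES[mat[i]].tobytes().decode() for i in range(nseq)]
    ids = [f"seq{i + 1:04d}" for i in range(nseq)]
    aln = Alignment(ids=ids, rows=rows, reference_id=ids[0])
    truth = {
        "invariant_columns": inv,
        "target_identity": target,
        "dominance": c,
        "seed": params.seed,
    }
    return aln, truth


def mean_pairwise_identity(aln: Alignment) -> float:
    """Mean over all sequence pairs of the fraction of equal columns."""
    mat = np.array([list(r) for r in aln.rows])
    n = len(aln.rows)
    total = 0.0
    pairs = 0
    for i in range(n):
        eq = (mat[i + 1 :] == mat[i]).mean(axis=1)
        total += float(eq.sum())
        pairs += eq.size
    return total / pairs


def write_genome_dataset(
    genomes: list[Genome], truth: SimTruth, out_dir: str | Path
) -> None:
    """Write PTT tables, protein FASTA, domain/clade TSVs and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for genome in genomes:
        for rep in genome.replicons:
            with open(out / f"{genome.genome_id}.ptt", "w") as fh:
                write_ptt(rep, fh)
    with open(out / "proteins.faa", "w") as fh:
        write_fasta(protein_map(genomes), fh)
    truth_domains = domain_table(genomes, truth)
    with open(out / "domains.tsv", "w") as fh:
        for gene_id in sorted(truth_domains):
            fh.write(f"{gene_id}\t{truth_domains[gene_id]}\n")
    with open(out / "clades.tsv", "w") as fh:
        for genome in genomes:
            fh.write(f"{genome.genome_id}\t{genome.clade}\n")
    with open(out / "truth.json", "w") as fh:
        fh.write(truth.to_json())
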