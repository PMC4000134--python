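"""End-to-end orchestration of the two workflows.

``run_context_analysis`` chains genome reading, anchor location,
neighborhood extraction, homolog clustering, cluster annotation, operon
calling, cross-genome association and the co-occurrence null model into a
single deterministic report.  ``run_conservation_analysis`` chains
alignment scoring, 1-9 grading, reference mapping and (optionally) spatial
clustering on a structure.  File-based wrappers read the on-disk layout the
simulator writes and emit TSV tables plus a JSON report; identical inputs
and configuration give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .association import (
    AssociationTable,
    NullModelParams,
    cooccurrence_p_analytic,
    phyletic_spread,
    summarize_associations,
)
from .clustering import annotate_clusters, cluster_proteins, membership_map
from .conservation import (
    Alignment,
    bin_grades,
    compute_conservation,
    conserved_spatial_cluster,
    map_to_reference,
    read_alignment,
    read_structure_coords,
)
from .genome_io import Genome, read_fasta, read_ptt
from .neighborhood import extract_neighborhood, find_anchors
from .operon import anchor_operon_context, call_operons

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of both workflows, with module defaults."""

    # context workflow inputs
    genomes_dir: Optional[str] = None
    proteins_fasta: Optional[str] = None
    domains_tsv: Optional[str] = None
    clades_tsv: Optional[str] = None
    anchor_family: str = "DUF4910 peptidase-like"
    window: int = 20
    orient_by_strand: bool = False
    identity_min: float = 0.30
    coverage_min: float = 0.60
    operon_max_gap: int = 200
    null_N: int = 4000
    null_k: int = 5
    min_support_fraction: float = 0.5
    # conservation workflow inputs
    alignment: Optional[str] = None
    alignment_format: str = "fasta"
    reference_id: Optional[str] = None
    pdb: Optional[str] = None
    chain: str = "A"
    min_grade: int = 9
    distance_cutoff: float = 8.0
    residue_offset: int = 0
    # shared
    seed: int = 0
    out_dir: str = "genecontext_out"

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ContextResult:
    report: dict
    table: AssociationTable
    neighborhoods: list = field(default_factory=list)
    clusters: list = field(default_factory=list)
    annotations: list = field(default_factory=list)
    operons: dict = field(default_factory=dict)


def run_context_analysis(
    genomes: list[Genome],
    proteins: dict[str, str],
    domains: dict[str, str],
    clades: dict[str, str],
    config: RunConfig,
) -> ContextResult:
    """Anchors -> neighborhoods -> clusters -> operons -> associations -> p.

    ``domains`` (gene -> architecture) both designates the anchor family
    and annotates neighbor clusters; ``proteins`` supplies sequences for
    genes whose records carry none.
    """
    t0 = time.perf_counter()
    anchors = find_anchors(genomes, domains, config.anchor_family)
    if not anchors.members:
        raise ValueError(
            f"no genes annotated with anchor family {config.anchor_family!r}"
        )
    rep_of = {
        rep.replicon_id: rep for gm in genomes for rep in gm.replicons
    }
    gene_replicon = {
        g.gene_id: rep.replicon_id
        for gm in genomes for rep in gm.replicons for g in rep.genes
    }

    neighborhoods = []
    for _genome_id, gene_id in anchors.members:
        rep = rep_of[gene_replicon[gene_id]]
        neighborhoods.append(
            extract_neighborhood(
                rep, gene_id, window=config.window,
                orient_by_strand=config.orient_by_strand,
            )
        )
    logger.info("extracted %d neighborhoods [%.2fs]",
                len(neighborhoods), time.perf_counter() - t0)

    seqs: dict[str, str] = {}
    for nb in neighborhoods:
        for gene in nb.all_genes():
            seq = gene.protein_seq or proteins.get(gene.gene_id)
            if not seq:
                raise ValueError(f"no protein sequence for {gene.gene_id}")
            seqs[gene.gene_id] = seq
    t1 = time.perf_counter()
    clusters = cluster_proteins(
        seqs, identity_min=config.identity_min, coverage_min=config.coverage_min
    )
    annotations = annotate_clusters(clusters, domains)
    logger.info("clustered %d proteins into %d clusters [%.2fs]",
                len(seqs), len(clusters), time.perf_counter() - t1)

    operons = {
        gm.genome_id: [
            op for rep in gm.replicons
            for op in call_operons(rep, max_gap=config.operon_max_gap)
        ]
        for gm in genomes
    }
    table = summarize_associations(
        neighborhoods, membership_map(clusters), annotations, clades, operons
    )

    anchor_genomes = sorted({g for g, _ in anchors.members})
    min_support = max(1, math.ceil(config.min_support_fraction * len(anchor_genomes)))
    spread = phyletic_spread(table, min_support=min_support)
    embedded = 0
    for nb in neighborhoods:
        ctx = anchor_operon_context(nb, operons[nb.genome_id])
        if ctx.embedded:
            embedded += 1

    null = NullModelParams(
        N=config.null_N, window_total=2 * config.window, k=config.null_k,
        seed=config.seed,
    )
    p_analytic = cooccurrence_p_analytic(null)

    report = {
        "tool": "genecontext",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "anchor_family": config.anchor_family,
            "window": config.window,
            "identity_min": config.identity_min,
            "coverage_min": config.coverage_min,
            "operon_max_gap": config.operon_max_gap,
            "null_N": config.null_N,
            "null_k": config.null_k,
            "min_support_fraction": config.min_support_fraction,
        },
        "n_genomes": len(genomes),
        "n_anchor_genomes": len(anchor_genomes),
        "n_neighborhoods": len(neighborhoods),
        "n_clusters": len(clusters),
        "anchor_family": table.anchor_family,
        "n_embedded_anchors": embedded,
        "associations": [
            {
                "family": row.family_label,
                "genome_support": row.genome_support,
                "support_fraction": row.genome_support / len(anchor_genomes),
                "n_clades": len(row.clades),
                "clades": row.clades,
                "operonic_support": row.operonic_support,
            }
            for row in table.rows
        ],
        "conserved_families": sorted(
            row.family_label for row in table.rows
            if row.genome_support >= min_support
        ),
        "phyletic_spread": spread,
        "cooccurrence_p_analytic": p_analytic,
    }
    return ContextResult(
        report=report, table=table, neighborhoods=neighborhoods,
        clusters=clusters, annotations=annotations, operons=operons,
    )


def load_genome_dataset(
    config: RunConfig,
) -> tuple[list[Genome], dict[str, str], dict[str, str], dict[str, str]]:
    """Read the on-disk layout: per-genome PTT files + TSV side tables."""
    gdir = Path(config.genomes_dir)
    if not gdir.is_dir():
        raise ValueError(f"genome directory {gdir} does not exist")
    ptts = sorted(gdir.glob("*.ptt"))
    if not ptts:
        raise ValueError(f"no .ptt files in {gdir}")
    clades = _read_two_col(config.clades_tsv) if config.clades_tsv else {}
    genomes = []
    for ptt in ptts:
        genome_id = ptt.stem
        with open(ptt) as fh:
            rep = read_ptt(fh, genome_id=genome_id, replicon_id=f"{genome_id}_chr")
        genomes.append(
            Genome(genome_id=genome_id, clade=clades.get(genome_id, ""),
                   replicons=[rep])
        )
    proteins = {}
    if config.proteins_fasta:
        with open(config.proteins_fasta) as fh:
            proteins = read_fasta(fh)
    domains = _read_two_col(config.domains_tsv) if config.domains_tsv else {}
    return genomes, proteins, domains, clades


def _read_two_col(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, value = line.split("\t", 1)
            out[key] = value
    return out


def _header(config: RunConfig) -> str:
    return (f"# genecontext {__version__} seed={config.seed} "
            f"window={config.window} identity_min={config.identity_min} "
            f"coverage_min={config.coverage_min} max_gap={config.operon_max_gap}\n")


def run_context_pipeline(config: RunConfig) -> dict:
    """File-based context workflow: read inputs, write TSVs + report.json."""
    genomes, proteins, domains, clades = load_genome_dataset(config)
    result = run_context_analysis(genomes, proteins, domains, clades, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "associations.tsv", "w") as fh:
        fh.write(_header(config))
        fh.write("family\tgenome_support\tn_clades\toperonic_support\tclades\tgenomes\n")
        for row in result.table.rows:
            fh.write(
                f"{row.family_label}\t{row.genome_support}\t{len(row.clades)}\t"
                f"{row.operonic_support}\t{','.join(row.clades)}\t"
                f"{','.join(row.genomes)}\n"
            )
    label_of = {a.cluster_id: a for a in result.annotations}
    with open(out / "clusters.tsv", "w") as fh:
        fh.write(_header(config))
        fh.write("cluster_id\tmember_id\trepresentative\tlabel\tsupport\n")
        for cl in result.clusters:
            ann = label_of[cl.cluster_id]
            for m in cl.member_ids:
                rep = "1" if m == cl.representative_id else "0"
                fh.write(f"{cl.cluster_id}\t{m}\t{rep}\t{ann.label}\t{ann.support:.3f}\n")
    with open(out / "neighborhoods.tsv", "w") as fh:
        fh.write(_header(config))
        fh.write("anchor_id\tgenome_id\tneighbor_id\toffset\tstrand\tproduct\n")
        for nb in result.neighborhoods:
            rows = (
                [(g, -i) for i, g in enumerate(nb.neighbors_5prime, 1)][::-1]
                + [(nb.anchor, 0)]
                + [(g, i) for i, g in enumerate(nb.neighbors_3prime, 1)]
            )
            for g, off in rows:
                fh.write(
                    f"{nb.anchor.gene_id}\t{nb.genome_id}\t{g.gene_id}\t{off}\t"
                    f"{g.strand}\t{g.product}\n"
                )
    with open(out / "operons.tsv", "w") as fh:
        fh.write(_header(config))
        fh.write("operon_id\treplicon_id\tstrand\tn_genes\tgene_ids\n")
        for genome_id in sorted(result.operons):
            for op in result.operons[genome_id]:
                fh.write(
                    f"{op.operon_id}\t{op.replicon_id}\t{op.strand}\t"
                    f"{len(op.gene_ids)}\t{','.join(op.gene_ids)}\n"
                )
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return result.report


@dataclass
class ConservationResult:
    report: dict
    residue_grades: dict[int, Optional[int]]
    clusters: list = field(default_factory=list)


def run_conservation_analysis(
    aln: Alignment,
    config: RunConfig,
    pdb_text: Optional[str] = None,
) -> ConservationResult:
    """Scores -> 1-9 grades -> reference residues -> spatial clusters."""
    profile = bin_grades(compute_conservation(aln))
    residue_grades = map_to_reference(profile, aln, offset=config.residue_offset)
    clusters = []
    if pdb_text is not None:
        coords = read_structure_coords(pdb_text, chain=config.chain)
        clusters = conserved_spatial_cluster(
            residue_grades, coords,
            min_grade=config.min_grade, cutoff=config.distance_cutoff,
        )
    else:
        logger.info("no structure supplied; skipping spatial clustering")
    n_graded = sum(1 for g in profile.grades if g is not None)
    report = {
        "tool": "genecontext",
        "version": __version__,
        "parameters": {
            "reference_id": aln.reference_id,
            "min_grade": config.min_grade,
            "distance_cutoff": config.distance_cutoff,
            "residue_offset": config.residue_offset,
        },
        "n_sequences": aln.n_sequences,
        "n_columns": aln.n_columns,
        "n_graded_columns": n_graded,
        "n_invariant_columns": len(profile.invariant_columns),
        "grade9_residues": sorted(
            r for r, g in residue_grades.items() if g == 9
        ),
        "spatial_clusters": [
            {
                "residues": c.residue_numbers,
                "size": len(c.residue_numbers),
                "diameter": round(c.diameter, 3),
            }
            for c in clusters
        ],
    }
    return ConservationResult(
        report=report, residue_grades=residue_grades, clusters=clusters
    )


def run_conservation_pipeline(config: RunConfig) -> dict:
    """File-based conservation workflow: grade TSV, cluster TSV, JSON."""
    if not config.alignment or not config.reference_id:
        raise ValueError("conservation workflow needs an alignment and reference id")
    with open(config.alignment) as fh:
        aln = read_alignment(fh, config.reference_id, fmt=config.alignment_format)
    pdb_text = None
    if config.pdb:
        pdb_text = Path(config.pdb).read_text()
    result = run_conservation_analysis(aln, config, pdb_text=pdb_text)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "residue_grades.tsv", "w") as fh:
        fh.write(f"# genecontext {__version__} reference={config.reference_id} "
                 f"offset={config.residue_offset}\n")
        fh.write("residue_number\tgrade\n")
        for r in sorted(result.residue_grades):
            g = result.residue_grades[r]
            fh.write(f"{r}\t{g if g is not None else 'NA'}\n")
    with open(out / "conserved_clusters.tsv", "w") as fh:
        fh.write(f"# genecontext {__version__} min_grade={config.min_grade} "
                 f"cutoff={config.distance_cutoff}\n")
        fh.write("cluster_index\tsize\tdiameter\tresidues\n")
        for i, c in enumerate(result.clusters, 1):
            fh.write(f"{i}\t{len(c.residue_numbers)}\t{c.diameter:.3f}\t"
                     f"{','.join(map(str, c.residue_numbers))}\n")
    with open(out / "conservation_report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return result.report
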