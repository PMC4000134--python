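"""Cross-genome aggregation of neighborhood content and the co-occurrence
null model.

``summarize_associations`` turns per-genome neighborhoods plus cluster
annotations into a table of recurrent families with genome support, clade
(phyletic) spread and operonic support.  The null model asks how likely k
designated family genes are to land, by chance, inside the anchor's
neighborhood window when placed uniformly without replacement among the
other gene slots of an N-gene genome; both the exact product formula and a
seeded Monte Carlo estimator with Clopper-Pearson bounds are provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .clustering import UNANNOTATED, ClusterAnnotation
from .neighborhood import Neighborhood
from .operon import Operon, gene_to_operon

logger = logging.getLogger(__name__)


@dataclass
class AssociationRow:
    family_label: str
    genome_support: int
    genomes: list[str]
    clades: list[str]
    operonic_support: int


@dataclass
class AssociationTable:
    anchor_family: str
    rows: list[AssociationRow] = field(default_factory=list)


@dataclass
class NullModelParams:
    """Parameters of the sampling-without-replacement co-occurrence null.

    ``N`` interchangeable gene slots per genome, one holding the anchor;
    ``window_total`` neighborhood slots around it (2 x per-side window);
    ``k`` designated family genes placed uniformly without replacement in
    the N-1 non-anchor slots.
    """

    N: int = 4000
    window_total: int = 40
    k: int = 5
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k and self.window_total < self.N):
            raise ValueError("need 1 <= k and window_total < N")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def summarize_associations(
    neighborhoods: list[Neighborhood],
    membership: dict[str, str],
    annotations: list[ClusterAnnotation],
    clade_map: dict[str, str],
    operons: Optional[dict[str, list[Operon]]] = None,
    include_unannotated: bool = False,
) -> AssociationTable:
    """Aggregate neighborhoods into one association row per non-anchor family.

    ``membership`` maps every neighborhood gene to its cluster;
    ``annotations`` label the clusters; families are annotation labels.  A
    family present several times in one genome counts that genome once.
    Clusters labelled "unannotated" are pooled background and excluded
    unless ``include_unannotated`` is set.  Rows are sorted by genome
    support descending, then label.
    """
    missing = sorted(
        {g.gene_id for nb in neighborhoods for g in nb.all_genes()} - set(membership)
    )
    if missing:
        raise ValueError(f"genes missing from membership: {missing}")
    label_of = {a.cluster_id: a.label for a in annotations}

    anchor_labels = {
        label_of.get(membership[nb.anchor.gene_id], UNANNOTATED) for nb in neighborhoods
    }
    anchor_family = "|".join(sorted(anchor_labels))

    support: dict[str, set[str]] = {}
    operonic: dict[str, set[str]] = {}
    for nb in neighborhoods:
        genome = nb.genome_id
        op_lookup = (
            gene_to_operon(operons.get(genome, [])) if operons is not None else {}
        )
        anchor_op = op_lookup.get(nb.anchor.gene_id)
        for gene in nb.neighbors_5prime + nb.neighbors_3prime:
            label = label_of.get(membership[gene.gene_id], UNANNOTATED)
            if label in anchor_labels:
                continue
            if label == UNANNOTATED and not include_unannotated:
                continue
            support.setdefault(label, set()).add(genome)
            if anchor_op is not None and op_lookup.get(gene.gene_id) == anchor_op:
                operonic.setdefault(label, set()).add(genome)

    rows = []
    for label, genomes in support.items():
        genome_list = sorted(genomes)
        clades = sorted({clade_map[g] for g in genome_list if g in clade_map})
        rows.append(
            AssociationRow(
                family_label=label,
                genome_support=len(genome_list),
                genomes=genome_list,
                clades=clades,
                operonic_support=len(operonic.get(label, set())),
            )
        )
    rows.sort(key=lambda r: (-r.genome_support, r.family_label))
    return AssociationTable(anchor_family=anchor_family, rows=rows)


def phyletic_spread(
    table: AssociationTable, min_support: int = 1
) -> dict[str, dict]:
    """Clade spread of every family with genome support >= min_support."""
    out: dict[str, dict] = {}
    for row in table.rows:
        if row.genome_support >= min_support:
            out[row.family_label] = {
                "n_clades": len(row.clades),
                "clades": list(row.clades),
                "genome_support": row.genome_support,
            }
    return out


def cooccurrence_p_analytic(params: NullModelParams) -> float:
    """Exact probability that all k designated genes fall in the window.

    p = prod_{i=0}^{k-1} (window_total - i) / (N - 1 - i), evaluated in log
    space so values far below 1e-300 remain representable on the way (the
    final product here never underflows for sensible genome sizes).
    Returns 0 with a warning when k exceeds the window.
    """
    if params.k > params.window_total:
        logger.warning(
            "k=%d exceeds window_total=%d; co-occurrence impossible",
            params.k, params.window_total,
        )
        return 0.0
    log_p = sum(
        math.log(params.window_total - i) - math.log(params.N - 1 - i)
        for i in range(params.k)
    )
    return math.exp(log_p)


def cooccurrence_p_enumerate(params: NullModelParams) -> float:
    """Brute-force check of the analytic formula by exhaustive enumeration.

    Counts favorable k-subsets of the N-1 non-anchor slots directly; only
    feasible for small N, and kept as an independent oracle.
    """
    from itertools import combinations

    slots = params.N - 1
    favorable = total = 0
    for combo in combinations(range(slots), params.k):
        total += 1
        if all(c < params.window_total for c in combo):
            favorable += 1
    return favorable / total


def cooccurrence_p_montecarlo(
    params: NullModelParams,
) -> tuple[float, tuple[float, float]]:
    """Monte Carlo estimate of the co-occurrence probability.

    Draws ``n_samples`` placements of k genes without replacement among the
    N-1 non-anchor slots (the first ``window_total`` slots are the
    neighborhood) and reports the favorable fraction with exact
    Clopper-Pearson 95% bounds.  Reproducible given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    slots = params.N - 1
    if params.k >= slots:
        # every slot drawn: success is deterministic
        estimate = 1.0 if params.window_total >= slots else 0.0
        return estimate, (estimate, estimate)
    hits = 0
    # keep the (chunk x slots) uniform matrix under ~160 MB
    chunk = max(1, min(50_000, 20_000_000 // max(slots, 1)))
    remaining = params.n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        # k smallest of a random permutation == uniform k-subset; vectorized
        draws = rng.random((m, slots)).argpartition(params.k, axis=1)[:, : params.k]
        hits += int((draws < params.window_total).all(axis=1).sum())
        remaining -= m
    n = params.n_samples
    estimate = hits / n
    lo = 0.0 if hits == 0 else float(stats.beta.ppf(0.025, hits, n - hits + 1))
    hi = 1.0 if hits == n else float(stats.beta.ppf(0.975, hits + 1, n - hits))
    return estimate, (lo, hi)
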