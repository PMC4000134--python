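"""Greedy single-linkage homolog clustering and cluster annotation.

The clustering mimics BLASTCLUST semantics: two proteins are linked when a
global alignment (BLOSUM62, affine gaps 11/1, terminal gaps free) reaches
both an identity and a coverage threshold; clusters are the connected
components of that link graph, built greedily over sequences in
deterministic (length-descending, id-ascending) order so the result is
independent of input order.

A shared-4-mer screen skips the alignment for long sequence pairs that
cannot plausibly be homologs; it is bypassed for short sequences, where a
true match can lack shared 4-mers.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import VALID_AA

# sequence pairs both at least this long go through the k-mer prescreen
_PRESCREEN_MIN_LEN = 40
_PRESCREEN_K = 4
_PRESCREEN_MIN_SHARED = 2


@dataclass(frozen=True)
class PairwiseIdentity:
    identity: float
    coverage: float
    aligned_columns: int


@dataclass
class ProteinCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str


@dataclass
class ClusterAnnotation:
    cluster_id: str
    label: str
    support: float


UNANNOTATED = "unannotated"


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # terminal gaps free: approximates length-coverage behaviour of a
    # local-alignment-based clusterer while staying a global DP
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _validate(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - VALID_AA
    if bad:
        raise ValueError(f"{name}: illegal characters {sorted(bad)}")


def pairwise_identity(seq_a: str, seq_b: str) -> PairwiseIdentity:
    """Percent identity and coverage from one optimal global alignment.

    Identity is identical residue pairs over aligned columns between the
    first and last aligned pair (terminal gap columns excluded, internal
    gap columns included).  Coverage is the aligned span of the shorter
    sequence over its length.  Symmetric in its arguments.
    """
    _validate(seq_a, "seq_a")
    _validate(seq_b, "seq_b")
    # fix argument order so the chosen optimal alignment is symmetric
    if (len(seq_a), seq_a) > (len(seq_b), seq_b):
        seq_a, seq_b = seq_b, seq_a
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return PairwiseIdentity(identity=0.0, coverage=0.0, aligned_columns=0)
    matched = 0
    identical = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        matched += a1 - a0
        identical += sum(
            1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]) if x == y
        )
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    columns = span_a + span_b - matched
    shorter = min(len(seq_a), len(seq_b))
    short_span = span_a if len(seq_a) <= len(seq_b) else span_b
    return PairwiseIdentity(
        identity=float(identical / columns) if columns else 0.0,
        coverage=float(short_span / shorter),
        aligned_columns=int(columns),
    )


def _kmers(seq: str, k: int = _PRESCREEN_K) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _linked(
    seq_a: str,
    seq_b: str,
    kmers_a: frozenset[str],
    kmers_b: frozenset[str],
    identity_min: float,
    coverage_min: float,
) -> bool:
    if len(seq_a) >= _PRESCREEN_MIN_LEN and len(seq_b) >= _PRESCREEN_MIN_LEN:
        if len(kmers_a & kmers_b) < _PRESCREEN_MIN_SHARED:
            return False
    pid = pairwise_identity(seq_a, seq_b)
    return pid.identity >= identity_min and pid.coverage >= coverage_min


def cluster_proteins(
    seqs: dict[str, str],
    identity_min: float = 0.30,
    coverage_min: float = 0.60,
) -> list[ProteinCluster]:
    """Partition proteins into single-linkage identity clusters.

    Sequences are processed longest first (ties by id); each joins every
    existing cluster containing a linked member, merging those clusters if
    there are several, or seeds a new one.  The output therefore equals the
    connected components of the thresholded pairwise-link graph and does
    not depend on dict insertion order.  Clusters are returned sorted by
    size descending then representative id, with the representative being
    the longest member (ties by id).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    for sid, seq in seqs.items():
        _validate(seq, sid)
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    kmers = {sid: _kmers(seqs[sid]) for sid in order}

    clusters: list[list[str]] = []
    for sid in order:
        hits = []
        for ci, members in enumerate(clusters):
            if any(
                _linked(seqs[sid], seqs[m], kmers[sid], kmers[m],
                        identity_min, coverage_min)
                for m in members
            ):
                hits.append(ci)
        if not hits:
            clusters.append([sid])
        else:
            merged = clusters[hits[0]]
            merged.append(sid)
            for ci in reversed(hits[1:]):
                merged.extend(clusters.pop(ci))

    out = []
    for members in clusters:
        rep = min(members, key=lambda i: (-len(seqs[i]), i))
        out.append((sorted(members), rep))
    out.sort(key=lambda t: (-len(t[0]), t[1]))
    return [
        ProteinCluster(cluster_id=f"C{i + 1:04d}", member_ids=members,
                       representative_id=rep)
        for i, (members, rep) in enumerate(out)
    ]


def membership_map(clusters: list[ProteinCluster]) -> dict[str, str]:
    """gene_id -> cluster_id over a cluster list."""
    return {m: c.cluster_id for c in clusters for m in c.member_ids}


def annotate_clusters(
    clusters: list[ProteinCluster],
    domains: dict[str, str],
) -> list[ClusterAnnotation]:
    """Label each cluster by the majority domain architecture of members.

    ``domains`` maps member ids to architecture strings (e.g.
    ``"DUF3880 + Glycosyltransferase"``).  The label is the most frequent
    architecture among annotated members (ties broken lexicographically)
    and support is its frequency among annotated members.  Clusters with no
    annotated member are labelled ``"unannotated"`` with support 0.
    """
    out = []
    for cluster in clusters:
        counts: dict[str, int] = {}
        for m in cluster.member_ids:
            if m in domains:
                counts[domains[m]] = counts.get(domains[m], 0) + 1
        if not counts:
            out.append(ClusterAnnotation(cluster.cluster_id, UNANNOTATED, 0.0))
            continue
        n_annot = sum(counts.values())
        label = min(counts, key=lambda a: (-counts[a], a))
        out.append(
            ClusterAnnotation(cluster.cluster_id, label, counts[label] / n_annot)
        )
    return out
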