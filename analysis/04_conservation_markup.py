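#!/usr/bin/env python
"""Grade alignment conservation and map it onto a (synthetic) structure.

Simulates a homolog alignment in the style of the anchor family's
metallopeptidase-like domain — 82 sequences in the 35-60% identity band
over 246 columns, with 10 planted invariant columns standing in for the
active-site and other critical residues — grades every column 1-9, and
projects the grades onto a synthetic C-alpha trace in which the planted
residues are spatially adjacent (mimicking an active-site cleft) and the
rest lie on an extended curve.  The expected outcome is that the planted
positions surface as grade 9 and form one spatial cluster, the
alignment-to-structure route for nominating a putative active site.

Outputs: results/conservation/ (residue_grades.tsv, conserved_clusters.tsv,
conservation_report.json) and the synthetic structure under
scratch/synthetic_domain.pdb.
"""

import numpy as np
from pathlib import Path

from genecontext.conservation import read_alignment  # noqa: F401  (format ref)
from genecontext.pipeline import RunConfig, run_conservation_analysis
from genecontext.simulate import (
    AlignmentSimParams,
    mean_pairwise_identity,
    simulate_alignment,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "conservation"
SCRATCH = ROOT / "scratch"
SEED = 7

N_COLUMNS = 246          # size of the metallopeptidase-like domain
INVARIANT = [10, 35, 60, 88, 104, 131, 160, 189, 195, 224]


def synthetic_ca_trace(n_residues: int, clustered: list[int],
                       rng: np.random.Generator) -> str:
    """A PDB-format CA trace: clustered residues in a 6 A ball, the rest on
    an extended helix-like curve far away.  Synthetic stand-in for a real
    domain structure."""
    lines = []
    t = 0.0
    for resnum in range(1, n_residues + 1):
        if resnum in clustered:
            xyz = rng.uniform(-3.0, 3.0, 3)
        else:
            t += 1.0
            xyz = np.array([40 + 1.5 * t, 10 * np.cos(t / 2), 10 * np.sin(t / 2)])
        lines.append(
            f"ATOM  {resnum:5d}  CA  ALA A{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00 20.00           C"
        )
    return "\n".join(lines) + "\nEND\n"


def main() -> None:
    aln, truth = simulate_alignment(AlignmentSimParams(
        n_sequences=82, n_columns=N_COLUMNS, invariant_columns=INVARIANT,
        identity_band=(0.35, 0.60), seed=SEED))
    print(f"simulated {aln.n_sequences} homologs x {aln.n_columns} columns, "
          f"mean pairwise identity {mean_pairwise_identity(aln):.2f}")

    rng = np.random.default_rng(SEED)
    clustered_residues = [c + 1 for c in INVARIANT]  # reference is ungapped
    pdb_text = synthetic_ca_trace(N_COLUMNS, clustered_residues, rng)
    SCRATCH.mkdir(exist_ok=True)
    (SCRATCH / "synthetic_domain.pdb").write_text(pdb_text)

    config = RunConfig(chain="A", min_grade=9, distance_cutoff=8.0,
                       out_dir=str(RESULTS))
    result = run_conservation_analysis(aln, config, pdb_text=pdb_text)

    grade9 = result.report["grade9_residues"]
    planted = set(clustered_residues)
    print(f"grade-9 residues: {len(grade9)} "
          f"({len(planted & set(grade9))}/{len(planted)} planted recovered)")
    top = result.report["spatial_clusters"][0] if result.report["spatial_clusters"] else None
    if top:
        print(f"largest conserved spatial cluster: {top['size']} residues, "
              f"diameter {top['diameter']} A -> putative active-site patch")
        print(f"  residues: {top['residues']}")

    RESULTS.mkdir(parents=True, exist_ok=True)
    with open(RESULTS / "residue_grades.tsv", "w") as fh:
        fh.write("# synthetic domain alignment, grades 1-9 (9 = most conserved)\n")
        fh.write("residue_number\tgrade\n")
        for r in sorted(result.residue_grades):
            g = result.residue_grades[r]
            fh.write(f"{r}\t{g if g is not None else 'NA'}\n")
    with open(RESULTS / "conserved_clusters.tsv", "w") as fh:
        fh.write("cluster_index\tsize\tdiameter\tresidues\n")
        for i, c in enumerate(result.clusters, 1):
            fh.write(f"{i}\t{len(c.residue_numbers)}\t{c.diameter:.2f}\t"
                     f"{','.join(map(str, c.residue_numbers))}\n")
    import json

    with open(RESULTS / "conservation_report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    print(f"outputs: {RESULTS}")


if __name__ == "__main__":
    main()
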