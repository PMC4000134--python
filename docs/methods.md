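# Methods

This note documents the models behind `genecontext`, the parameters that
matter, what the synthetic benchmarks do and do not establish, and the
numerical choices a maintainer would want spelled out.

## Genome model and neighborhoods

Genes are 1-based inclusive coordinate intervals with a strand, sorted by
start (ties by end, then id) into a 0-based `rank` per replicon. All
neighborhood logic runs in rank space: a neighborhood is the anchor plus up
to `window` genes per side (default 20 per side, so 41 genes at most).
Rank, not base-pair, windows make the extraction robust to gene-length and
intergenic-length variation and match how neighbor counts are reported in
comparative-genomics practice.

Two conventions are deliberate:

- **5′/3′ sides follow replicon coordinate order by default** (lower ranks
  are the 5′ side), independent of the anchor's strand. This is
  reproducible and side-stable across genomes; `orient_by_strand=True`
  re-orients by the anchor's reading direction for analyses that need it.
- **Linear replicons truncate silently at their ends; circular replicons
  wrap** without ever reporting a gene twice (total capped at replicon
  size). Topology is honored only when the input declares it; linear is the
  conservative default.

GenBank `join(..)` locations collapse to their outermost span — the
pipeline consumes order and strand only. Only CDS features are modeled;
RNA genes and pseudogene features are outside the gene-count windows.

## Homolog clustering

Neighbor proteins are clustered by greedy single-linkage identity
clustering in the BLASTCLUST mold. The pair kernel is one optimal global
alignment (BLOSUM62, gap open 11 / extend 1, terminal gaps free), from
which

- identity = identical pairs / aligned columns between the first and last
  aligned pair (internal gap columns count, terminal gap columns do not);
- coverage = aligned span of the shorter sequence / its length.

Pairs link when identity ≥ `identity_min` (default 0.30) and coverage ≥
`coverage_min` (default 0.60). Sequences are processed longest-first (ties
by id) and each joins — and, when it matches several, merges — every
cluster containing a linked member. The output is therefore exactly the
connected components of the thresholded link graph, which makes it
independent of input order and lets tests compare it against a brute-force
component oracle; a plain "first matching cluster" greedy rule would not
have that property. Representative = longest member, ties by id.

Two performance choices: argument order into the aligner is canonicalized
so the chosen optimum is symmetric, and pairs in which both sequences have
≥ 40 residues must share ≥ 2 four-mers before an alignment is attempted
(BLAST-style word seeding; random ~100-residue pairs share ~0.06 four-mers
in expectation, related sequences at the simulator's 15% mutation rate
share ~half). The prescreen is bypassed for shorter sequences, where a
genuinely linked pair can lack shared words; on such sets the clustering is
exactly the exhaustive-DP component structure.

Cluster annotation is majority vote over the domain architectures of
annotated members (ties broken lexicographically), with support = majority
frequency among annotated members. Clusters with no annotated member are
the pooled `unannotated` background; the association table excludes them
from family rows by default because they are not families — an
`include_unannotated` flag restores them for diagnostics. Domain detection
itself (profile search) is consumed as a precomputed `protein → architecture`
table; the module's job is grouping and labelling, not HMM search.

## Operons

Putative operons are maximal runs of rank-adjacent, same-strand genes whose
intergenic gaps (next.start − prev.end − 1, floored at 0 for overlapping
genes) do not exceed `max_gap`. "Shares a promoter" is thus operationalized
as a distance proxy — the standard approach when no transcription data is
in play; the default 200 bp is in the range used by distance-based operon
predictors and is a flag, not a constant. Overlapping same-strand genes
always merge. Head-to-head (−,+) adjacent pairs within 300 bp are reported
as candidate bidirectional-promoter pairs but never merged. Operons
partition the replicon; raising `max_gap` can only coarsen the partition.

## Association table and null model

Associations aggregate per genome: a family present twice near one anchor
counts that genome once; clade (phyletic) spread is the number of distinct
clade labels among supporting genomes; operonic support counts genomes in
which a family member shares the anchor's operon.

Significance of a k-family co-occurrence is judged against sampling without
replacement: fix the anchor, treat the genome as N interchangeable gene
slots, place the k designated family genes uniformly without replacement
among the N − 1 non-anchor slots, and ask that all k land in the
w = 2·window neighborhood slots:

    p = prod_{i=0}^{k-1} (w - i) / (N - 1 - i)

evaluated in log space. Defaults N = 4000 (an average bacterial genome),
w = 40, k = 5 (the five linked sugar-enzyme families of the motivating
case), giving p ≈ 7.74e-11. The formula is verified exactly against
exhaustive enumeration for all N ≤ 12, w < N, k ≤ 3. A Monte Carlo
estimator (k-subsets of the N − 1 slots, favorable fraction,
Clopper–Pearson 95% bounds from the beta quantiles) validates the formula
in regimes where sampling has power (p ≥ ~10⁻³); probabilities at study
scale are far below Monte Carlo resolution at feasible sample counts and
are always reported from the analytic formula. The null is per genome;
combining evidence across genomes (which would only sharpen significance)
is deliberately not modeled, since no principled combination rule is
implied by the single-genome statement.

## Conservation scoring and structure mapping

Column conservation is a sequence-weighted relative entropy against a fixed
background composition (Robinson & Robinson frequencies, configurable):
sequences get position-based (Henikoff–Henikoff) weights with gaps counted
as a symbol class; per column, weighted residue frequencies f (gaps
excluded, renormalized) score

    S = sum_a f_a log2(f_a / q_a).

Columns with more than 50% gaps are unscored and ungraded. Scores are cut
at the 1/9 … 8/9 quantiles into grades 1–9 (9 = most conserved); equal
scores get equal grades, grades are monotone in score, and invariant
columns (a single residue type among non-gap symbols) are forced to grade
9 regardless of quantile edges. With fewer than nine scored columns the
grades spread score ranks evenly over 1–9 (a single scored column grades
9). This scoring is a transparent surrogate for Bayesian rate-inference
conservation servers: it preserves the decision structure (scores →
1–9 grades → structure markup → cluster detection) but per-column grade
agreement with any particular server's output is not claimed.

Grades project through the alignment's reference row onto residue numbers
1..L over the ungapped reference (plus a user offset for constructs whose
coordinate numbering differs, e.g. expression-tag remnants or disordered
termini). Structures are read from PDB ATOM records (via gemmi), one
representative atom per residue (CA by default; altlocs resolve to highest
occupancy, ties to the lowest altloc id). Conserved spatial clusters are
connected components of residues with grade ≥ `min_grade` (default 9)
under a pairwise-distance cutoff (default 8.0 Å between representative
atoms — about two contact shells of Cα atoms), sorted by size; cluster
diameter is the maximum intra-cluster distance.

## Synthetic benchmarks: what they emulate, and what they don't

`simulate_genomes` emulates the study conditions: genomes of 4000
protein-coding genes (one linear replicon, random strands, gene lengths
300–1500 bp, gaps 20–350 bp), one anchor-family gene per genome, and the
five planted families placed at distinct rank offsets within ±20 of the
anchor in a `presence_prob` fraction of genomes (default 0.9). With
probability `same_operon_prob` (default 0.75) the planted span is forced
onto the anchor's strand with 20–120 bp gaps, making the neighborhood
co-operonic. Decoy-family genes land at uniform ranks at 0.5 expected
occurrences per genome. Family proteins are point-mutated copies (15% per
position) of per-family random templates, so intra-family identity
(≈ 72% expected pairwise) is far above the clustering threshold while
inter-family identity is random — clustering recovery is a real test, not
a tautology. Clades are assigned round-robin from the clade list (default:
the ten bacterial clades of the motivating study). Everything is
deterministic given the seed and every planted fact is returned in a truth
object that tests read rather than re-derive.

`simulate_alignment` emits gap-free alignments: invariant columns carry one
residue; each variable column has a dominant residue whose weight is solved
from the requested mean pairwise identity band (match probability
m = c² + (1−c)²/19); columns that come out accidentally invariant are
re-touched so the emitted invariant set equals the planted set exactly.
Defaults (30 sequences × 100 columns, 10 invariant) are the recovery
benchmark; the analysis script uses 82 sequences at 35–60% identity to
mirror the motivating alignment's shape.

What passing these benchmarks does **not** show: robustness to real-genome
phenomena the generator omits — gene rearrangements and horizontal
transfer, paralog expansions, unequal clade sampling, gapped and
phylogenetically correlated alignments, domain fusions and splits. The
generators probe the pipeline's logic, not database-scale biology;
corpus-scale figures (thousands of genomes, hundreds of ortholog-bearing
genomes) are out of desk-scale reach by design.

## Problem sizes and runtime

The recovery benchmark runs 100 seeded datasets of 20 genomes × 500 genes
(4 clades, 5 planted families, presence 0.9, decoys 0.5/genome) — a
deliberate scale-down of the 4000-gene genome that leaves the neighborhood
logic untouched (windows are rank-based, and the null model is always
evaluated at its own N). It completes in ~2.5 minutes on one CPU, with the
families supported by ≥ 50% of genomes equal to the planted five in
≥ 95/100 runs (98/100 at the shipped seed). The analysis scripts run one
full-size corpus (20 × 4000 genes) in under a minute.

## Known limitations

- Pairwise identity comes from one optimal alignment; co-optimal
  alignments could score ties differently in principle (the canonical
  argument order makes the choice deterministic and symmetric).
- The k-mer prescreen is heuristic for long sequences: a true homolog pair
  straddling the 30% identity threshold with fewer than two shared 4-mers
  would be missed; at the thresholds and divergence levels the pipeline
  targets this is vanishingly rare.
- Operon calling is distance-only; it cannot separate same-strand adjacent
  transcription units with short spacers.
- Conservation grades are alignment-relative (quantile-binned within the
  alignment), so grade 9 in a shallow alignment is weaker evidence than in
  a deep one; the minimum of 5 sequences is a floor, not a recommendation.
- Gene-fusion detection, cross-genome p-value combination, and corrections
  for gene-family size biases are out of scope.
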