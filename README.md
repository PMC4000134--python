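# genecontext

Genomic-context inference for anchor gene families, plus
conservation-to-structure mapping. Built for the comparative-genomics
question "what does this uncharacterized protein family do?", answered the
way bacterial genomics answers it: look at what the gene's neighbors are,
across many genomes.

The motivating case is a bacterial metallopeptidase-like family (DUF4910,
anchored at *Clostridium acetobutylicum* CA_C2195) whose members sit, genome
after genome, in the middle of operons of sugar-modification enzymes —
evidence that the family acts in modified-carbohydrate biosynthesis rather
than as a peptidase. The package turns that style of argument into a
reusable, tested pipeline:

1. **Neighborhoods** — locate anchor-family genes and extract the 20 gene
   neighbors on each side (by gene rank, not base pairs) from PTT or GenBank
   gene tables.
2. **Homolog clustering** — group neighbor proteins by greedy single-linkage
   identity clustering (BLASTCLUST-style: global alignment with free terminal
   gaps, identity ≥ 30%, coverage ≥ 60% by default) and label each cluster by
   the majority domain architecture of its members.
3. **Operons** — merge rank-adjacent, same-strand genes with intergenic gaps
   ≤ 200 bp into putative operons; report head-to-head divergent pairs
   separately.
4. **Associations** — aggregate across genomes: which families recur near the
   anchor, in how many genomes, across how many clades (phyletic spread), and
   how often co-operonic with the anchor.
5. **Significance** — judge the co-occurrence against a
   sampling-without-replacement null: with *k* designated family genes placed
   uniformly among the N−1 non-anchor gene slots of an N-gene genome, the
   chance that all of them land in the w neighborhood slots is

   p = ∏<sub>i=0..k−1</sub> (w − i) / (N − 1 − i).

   For N = 4000, w = 40 (±20 genes) and k = 5 this gives p ≈ 7.7 × 10⁻¹¹ —
   five sugar-enzyme families next to the anchor is not chance.
6. **Conservation markup** — score homolog-alignment columns by
   sequence-weighted relative entropy, bin them into conservation grades 1–9
   (9 = most conserved, the ConSurf convention), project grades onto a
   reference structure, and report spatial clusters of grade-9 residues —
   the route from an alignment to a putative active site.

A synthetic-data module generates genomes with planted neighborhoods and
alignments with planted invariant columns, each with a machine-readable
truth table, so the whole pipeline is benchmarked without any downloads.

## Worked example

The numbered scripts under `analysis/` run the two workflows on a simulated
corpus (20 genomes × 4000 genes, five planted families at 90% presence,
ten clades):

```sh
python analysis/01_simulate_corpus.py
python analysis/02_context_inference.py
```

prints

```
genomes with anchors: 20
neighborhood proteins clustered into 703 clusters
anchors embedded mid-operon: 14/20
high-support families (>=50% of genomes):
  Aminosugar N-acetyltransferase: 20 genomes, 10 clades, co-operonic in 14
  Glycosyltransferase: 20 genomes, 10 clades, co-operonic in 14
  NDP-sugar epimerase/dehydratase: 20 genomes, 10 clades, co-operonic in 14
  SAM-dependent sugar methylase: 20 genomes, 10 clades, co-operonic in 14
  Sugar phosphate nucleotidyltransferase: 20 genomes, 10 clades, co-operonic in 14
recovered families match planted truth exactly (5/5)
chance co-occurrence p (N=4000, 40 slots, k=5): 7.740e-11
```

i.e. the pipeline recovers exactly the five planted sugar-enzyme families as
the high-support associations, finds them across all ten clades, sees the
anchor embedded mid-operon in most carrier genomes, and reports the
co-occurrence as far beyond chance. `analysis/03_null_model.py` tabulates
the null model (with enumeration and Monte Carlo cross-checks) and
`analysis/04_conservation_markup.py` runs the conservation workflow on a
simulated 82-homolog alignment (35–60% identity), recovering all 10 planted
invariant columns at grade 9 as one spatial cluster of diameter ~6 Å on a
synthetic Cα trace.

The same machinery is scriptable through the `genecontext` command
(`simulate`, `neighborhoods`, `cluster`, `operons`, `pvalue`, `conserve`,
`run-context`, `run-conservation`), e.g.:

```sh
genecontext pvalue --N 4000 --window 20 --k 5
{"p_analytic": 7.740015215429729e-11}
```

The 13-gene published neighborhood of CA_C2195 itself ships as an in-package
fixture (`genecontext.fixture_table2()`).

## Layout

- `src/genecontext/` — the library: `genome_io`, `neighborhood`,
  `clustering`, `operon`, `association`, `conservation`, `simulate`,
  `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end suites (pytest + hypothesis).
- `docs/methods.md` — models, parameter choices and limitations.
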