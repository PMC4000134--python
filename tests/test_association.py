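"""Association aggregation and the sampling-without-replacement null model."""

import pytest

from genecontext.association import (
    NullModelParams,
    cooccurrence_p_analytic,
    cooccurrence_p_enumerate,
    cooccurrence_p_montecarlo,
    phyletic_spread,
    summarize_associations,
)
from genecontext.clustering import ClusterAnnotation
from genecontext.neighborhood import extract_neighborhood
from genecontext.operon import call_operons
from genecontext.pipeline import RunConfig, run_context_analysis
from genecontext.simulate import (
    GenomeSimParams,
    clade_map,
    domain_table,
    protein_map,
    simulate_genomes,
)

from conftest import make_replicon


def _toy_inputs(n_genomes=3, clades=("firmicutes", "actinobacteria", "cyanobacteria")):
    """Three 5-gene genomes; gene at rank 2 is the anchor, rank 1 family F."""
    neighborhoods = []
    membership = {}
    clade_of = {}
    for i in range(n_genomes):
        rep = make_replicon(["+"] * 5, replicon_id=f"rep{i}")
        rep.genome_id = f"G{i}"
        for g in rep.genes:
            g.genome_id = f"G{i}"
            g.gene_id = f"G{i}_{g.gene_id}"
        rep.sort_and_rank()
        nb = extract_neighborhood(rep, f"G{i}_g003", window=2)
        neighborhoods.append(nb)
        membership[f"G{i}_g003"] = "CL_anchor"
        membership[f"G{i}_g002"] = "CL_F"
        for tag in ("g001", "g004", "g005"):
            membership[f"G{i}_{tag}"] = f"CL_bg_{i}_{tag}"
        clade_of[f"G{i}"] = clades[i % len(clades)]
    annotations = [
        ClusterAnnotation("CL_anchor", "anchor_fam", 1.0),
        ClusterAnnotation("CL_F", "family_F", 1.0),
    ]
    return neighborhoods, membership, annotations, clade_of


class TestSummarizeAssociations:
    def test_family_support_counts_genomes_once(self):
        neighborhoods, membership, annotations, clades = _toy_inputs()
        table = summarize_associations(neighborhoods, membership, annotations, clades)
        assert table.anchor_family == "anchor_fam"
        (row,) = table.rows
        assert row.family_label == "family_F"
        assert row.genome_support == 3
        assert row.clades == ["actinobacteria", "cyanobacteria", "firmicutes"]

    def test_single_genome_all_supports_one(self):
        neighborhoods, membership, annotations, clades = _toy_inputs(n_genomes=1)
        table = summarize_associations(neighborhoods, membership, annotations, clades)
        assert all(r.genome_support == 1 for r in table.rows)

    def test_missing_membership_is_an_error(self):
        neighborhoods, membership, annotations, clades = _toy_inputs()
        del membership["G0_g001"]
        with pytest.raises(ValueError, match="G0_g001"):
            summarize_associations(neighborhoods, membership, annotations, clades)

    def test_operonic_support_counted_per_genome(self):
        neighborhoods, membership, annotations, clades = _toy_inputs()
        operons = {
            nb.genome_id: call_operons(_replicon_of(nb)) for nb in neighborhoods
        }
        table = summarize_associations(
            neighborhoods, membership, annotations, clades, operons=operons
        )
        (row,) = table.rows
        assert row.operonic_support == 3

    def test_input_order_invariance(self):
        neighborhoods, membership, annotations, clades = _toy_inputs()
        a = summarize_associations(neighborhoods, membership, annotations, clades)
        b = summarize_associations(
            list(reversed(neighborhoods)), membership, annotations, clades
        )
        assert a == b

    def test_planted_families_recovered_from_simulator_truth(self):
        params = GenomeSimParams(
            n_genomes=10, genes_per_genome=200, presence_prob=1.0,
            clade_labels=["firmicutes", "actinobacteria", "cyanobacteria"],
            decoy_rate=0.0, seed=21,
        )
        genomes, truth = simulate_genomes(params)
        config = RunConfig(null_N=200)
        result = run_context_analysis(
            genomes, protein_map(genomes), domain_table(genomes, truth),
            clade_map(genomes), config,
        )
        top = {r.family_label for r in result.table.rows if r.genome_support == 10}
        assert top == set(params.planted_families)
        for row in result.table.rows:
            if row.family_label in top:
                assert len(row.clades) == 3


def _replicon_of(nb):
    from genecontext.genome_io import Replicon

    genes = nb.all_genes()
    return Replicon(replicon_id=genes[0].replicon_id, genome_id=nb.genome_id,
                    genes=list(genes))


class TestPhyleticSpread:
    def test_spread_counts_distinct_clades(self):
        neighborhoods, membership, annotations, clades = _toy_inputs()
        table = summarize_associations(neighborhoods, membership, annotations, clades)
        spread = phyletic_spread(table, min_support=2)
        assert spread["family_F"]["n_clades"] == 3

    def test_empty_table_empty_summary(self):
        from genecontext.association import AssociationTable

        assert phyletic_spread(AssociationTable(anchor_family="x")) == {}


class TestAnalyticNull:
    def test_certain_event(self):
        p = cooccurrence_p_analytic(NullModelParams(N=10, window_total=9, k=1))
        assert p == pytest.approx(1.0)

    def test_small_case_equals_enumeration_sixth(self):
        params = NullModelParams(N=10, window_total=4, k=2)
        assert cooccurrence_p_analytic(params) == pytest.approx(1 / 6)
        assert cooccurrence_p_enumerate(params) == pytest.approx(1 / 6)

    def test_study_scale_probability_below_1e9(self):
        p = cooccurrence_p_analytic(NullModelParams(N=4000, window_total=40, k=5))
        assert 0 < p < 1e-9

    def test_k_exceeding_window_returns_zero(self):
        assert cooccurrence_p_analytic(NullModelParams(N=50, window_total=3, k=5)) == 0.0

    def test_monotonicity_in_k_N_window(self):
        base = dict(N=100, window_total=20, k=3)
        p0 = cooccurrence_p_analytic(NullModelParams(**base))
        assert cooccurrence_p_analytic(NullModelParams(N=100, window_total=20, k=4)) < p0
        assert cooccurrence_p_analytic(NullModelParams(N=200, window_total=20, k=3)) < p0
        assert cooccurrence_p_analytic(NullModelParams(N=100, window_total=30, k=3)) > p0


class TestMonteCarlo:
    def test_certain_event_estimates_one(self):
        est, (lo, hi) = cooccurrence_p_montecarlo(
            NullModelParams(N=10, window_total=9, k=1, n_samples=1000, seed=4)
        )
        assert est == 1.0 and hi == 1.0

    def test_estimate_brackets_enumeration(self):
        params = NullModelParams(N=10, window_total=4, k=2, n_samples=100_000, seed=5)
        est, (lo, hi) = cooccurrence_p_montecarlo(params)
        assert lo <= 1 / 6 <= hi
        assert est == pytest.approx(1 / 6, abs=0.01)

    def test_reproducible_given_seed(self):
        params = NullModelParams(N=20, window_total=8, k=2, n_samples=20_000, seed=9)
        assert cooccurrence_p_montecarlo(params) == cooccurrence_p_montecarlo(params)

    def test_interval_coverage_over_seeds(self):
        """The 95% interval contains the exact value in nearly all runs."""
        params_base = dict(N=12, window_total=5, k=2, n_samples=5_000)
        exact = cooccurrence_p_analytic(NullModelParams(**params_base, seed=0))
        covered = 0
        for seed in range(100):
            _, (lo, hi) = cooccurrence_p_montecarlo(
                NullModelParams(**params_base, seed=seed)
            )
            covered += lo <= exact <= hi
        assert covered >= 93
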