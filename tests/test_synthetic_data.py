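"""Generator behaviour: trees, genomes, binding landscapes, evolution."""

import numpy as np
import pandas as pd
import pytest

from napmut import synthetic_data as sd
from napmut.ancestral_changes import InvalidParameterError
from napmut.binding_profiles import FIS_PHASES, PHASES, PROTEINS, overlap_fraction
from napmut.mutability_stats import scan_methylation_contexts

from _oracles import fourfold_count_by_codon_scan


class TestStrainTree:
    def test_topology_counts_and_supports(self):
        tree = sd.make_strain_tree(3, seed=1)
        leaves = tree.leaf_names
        assert len(leaves) == 4 and "outgroup" in leaves
        assert len(tree.internal_nodes) == 3  # rooted binary: n-1 joins + root
        assert all(n.length > 0 for n in tree.postorder() if n.parent is not None)

        big = sd.make_strain_tree(54, seed=7)
        assert len(big.leaf_names) == 55
        supports = [n.support for n in big.internal_nodes]
        assert all(s is not None and 0 <= s <= 100 for s in supports)

    def test_newick_deterministic(self):
        a = sd.make_strain_tree(10, seed=42).to_newick()
        b = sd.make_strain_tree(10, seed=42).to_newick()
        assert a == b
        assert a != sd.make_strain_tree(10, seed=43).to_newick()

    def test_rejects_tiny_ingroup(self):
        with pytest.raises(InvalidParameterError):
            sd.make_strain_tree(2, seed=0)

    def test_support_mixture_has_both_classes(self):
        tree = sd.make_strain_tree(40, seed=5, support_low_fraction=0.3)
        supports = [n.support for n in tree.internal_nodes if n is not tree.root]
        assert any(s < 98 for s in supports) and any(s >= 98 for s in supports)


class TestGenome:
    def test_no_genes_means_all_intergenic(self):
        g = sd.simulate_genome(sd.SimConfig(genome_length=2000, n_genes=0, seed=0))
        assert (g.gene_index == -1).all() and (g.degeneracy == -1).all()

    def test_fourfold_count_matches_codon_scan(self):
        g = sd.simulate_genome(sd.SimConfig(genome_length=12000, n_genes=12, seed=2))
        assert len(g.fourfold_positions) == fourfold_count_by_codon_scan(g)

    def test_deterministic_sequence(self):
        cfg = sd.SimConfig(genome_length=3000, n_genes=3, seed=9)
        assert sd.simulate_genome(cfg).sequence == sd.simulate_genome(cfg).sequence

    def test_genes_do_not_overlap(self):
        g = sd.simulate_genome(sd.SimConfig(genome_length=20000, n_genes=25, seed=4))
        genes = g.genes.sort_values("start")
        assert (genes.start.to_numpy()[1:] >= genes.end.to_numpy()[:-1]).all()

    def test_placement_error_when_genes_do_not_fit(self):
        with pytest.raises(sd.PlacementError):
            sd.simulate_genome(
                sd.SimConfig(genome_length=1000, n_genes=10, seed=0,
                             gene_length_range=(300, 300))
            )


@pytest.fixture(scope="module")
def genome():
    return sd.simulate_genome(sd.SimConfig(genome_length=200_000, n_genes=0, seed=3))


class TestBindingProfiles:

    def test_full_overlap_identical_sets(self, genome):
        cfg = sd.SimConfig(genome_length=200_000, n_genes=0, interphase_overlap=1.0, seed=3)
        profs = sd.simulate_binding_profiles(genome, cfg)
        for protein in PROTEINS:
            phases = FIS_PHASES if protein == "Fis" else PHASES
            anchor = profs[(protein, phases[-1])].intervals.tolist()
            for phase in phases:
                assert profs[(protein, phase)].intervals.tolist() == anchor

    def test_zero_overlap_disjoint(self, genome):
        cfg = sd.SimConfig(genome_length=200_000, n_genes=0, interphase_overlap=0.0, seed=3)
        profs = sd.simulate_binding_profiles(genome, cfg)
        f = overlap_fraction(profs[("H-NS", "stationary")], profs[("H-NS", "mid_exponential")])
        assert f == 0.0

    def test_half_overlap_calibrated(self, genome):
        cfg = sd.SimConfig(genome_length=200_000, n_genes=0, interphase_overlap=0.5, seed=3)
        profs = sd.simulate_binding_profiles(genome, cfg)
        for protein in ("H-NS", "IhfA", "IhfB"):
            f = overlap_fraction(profs[(protein, "stationary")], profs[(protein, "mid_exponential")])
            assert 0.45 <= f <= 0.55

    def test_fis_restricted_to_exponential_phases(self, genome):
        cfg = sd.SimConfig(genome_length=200_000, n_genes=0, seed=3)
        profs = sd.simulate_binding_profiles(genome, cfg)
        fis_phases = {phase for (prot, phase) in profs if prot == "Fis"}
        assert fis_phases == set(FIS_PHASES)

    def test_excessive_coverage_rejected(self, genome):
        with pytest.raises(InvalidParameterError):
            sd.simulate_binding_profiles(
                genome,
                sd.SimConfig(genome_length=200_000, n_genes=0,
                             binding_fraction_per_phase=1.0, seed=3),
            )


class TestEvolveAlignment:
    def test_zero_rates_identity(self):
        cfg = sd.SimConfig(genome_length=2000, n_genes=0, seed=1,
                           base_rates={t: 0.0 for t in sd.MUTATION_TYPES})
        g = sd.simulate_genome(cfg)
        tree = sd.make_strain_tree(4, seed=1)
        aln, truth = sd.evolve_alignment(g, tree, cfg)
        assert len(truth.true_changes) == 0
        for block in aln.blocks:
            for seq in block.sequences.values():
                assert seq == g.sequence

    def test_realized_rate_matches_binomial_expectation(self):
        # ~1e5 at-risk sites on the outgroup branch (whose parent is the
        # known root sequence): realised C->T fraction within 3 binomial SE
        rate = 0.2
        cfg = sd.SimConfig(
            genome_length=400_000, n_genes=0, seed=6, gc=0.5,
            base_rates={**{t: 0.0 for t in sd.MUTATION_TYPES}, "C>T": rate},
        )
        g = sd.simulate_genome(cfg)
        tree = sd.make_strain_tree(3, seed=6)
        aln, truth = sd.evolve_alignment(g, tree, cfg)
        out_branch = "outgroup"
        length = next(n.length for n in tree.leaves if n.name == out_branch)
        p = rate * length
        n_c = g.sequence.count("C")
        assert n_c > 90_000
        k = len(truth.true_changes.query("branch == @out_branch and from_base == 'C'"))
        se = np.sqrt(p * (1 - p) * n_c)
        assert abs(k - p * n_c) <= 3 * se

    def test_ccwgg_multiplier_recovered(self):
        from conftest import build_tree

        cfg = sd.SimConfig(
            genome_length=150_000, n_genes=0, seed=8, n_ccwgg_planted=4000,
            ccwgg_multiplier=10.0,
            base_rates={**{t: 0.0 for t in sd.MUTATION_TYPES}, "C>T": 0.15},
        )
        g = sd.simulate_genome(cfg)
        # a long outgroup branch gives enough focal events for SE(ratio) < 1
        tree = build_tree(
            (None, 0.0, 100.0,
             [(None, 0.01, 99.0,
               [("A", 0.01, None, []), ("B", 0.01, None, [])]),
              ("outgroup", 0.2, None, [])]),
            outgroup="outgroup",
        )
        aln, truth = sd.evolve_alignment(g, tree, cfg)
        census = scan_methylation_contexts(g.sequence)
        focal_fwd = set(census.ccwgg.query("strand == '+'").position)
        c_sites = {i for i, b in enumerate(g.sequence) if b == "C"}
        plain = c_sites - set(census.ccwgg.position)
        events = truth.true_changes.query("branch == 'outgroup' and from_base == 'C'")
        hit = set(events.site)
        rate_focal = len(hit & focal_fwd) / len(focal_fwd)
        rate_plain = len(hit & plain) / len(plain)
        assert 7.0 <= rate_focal / rate_plain <= 13.0

    def test_multiple_hit_regime_rejected(self):
        cfg = sd.SimConfig(genome_length=2000, n_genes=0, seed=1,
                           base_rates={**sd.DEFAULT_BASE_RATES, "C>T": 50.0})
        g = sd.simulate_genome(cfg)
        tree = sd.make_strain_tree(4, seed=1)
        with pytest.raises(InvalidParameterError, match="0.5"):
            sd.evolve_alignment(g, tree, cfg)

    def test_truth_matches_leaf_root_differences_in_low_rate_regime(self):
        cfg = sd.SimConfig(genome_length=30_000, n_genes=0, seed=12)
        g = sd.simulate_genome(cfg)
        tree = sd.make_strain_tree(6, seed=12)
        aln, truth = sd.evolve_alignment(g, tree, cfg)
        # at sites hit exactly once in the whole tree, the event is visible
        # as a root-vs-leaf difference in every descendant leaf
        counts = truth.true_changes.site.value_counts()
        once = truth.true_changes[truth.true_changes.site.map(counts) == 1]
        block = aln.blocks[0]
        leafsets = tree.leafsets()
        name_to_node = {n.name: n for n in tree.postorder()}
        for row in once.itertuples():
            node = name_to_node[row.branch]
            for leaf in leafsets[node]:
                assert block.sequences[leaf][row.site] == row.to_base
        # and sites never hit are identical to the root everywhere
        untouched = np.setdiff1d(np.arange(len(g)), truth.true_changes.site.unique())
        probe = untouched[:: max(1, len(untouched) // 500)]
        for s in probe:
            assert len({seq[s] for seq in block.sequences.values()}) == 1

    def test_implied_or_closed_form(self):
        effect = {("H-NS", "early", "C>T"): 2.0, ("H-NS", "late", "C>T"): 0.5}
        truth = sd.GroundTruth(true_binding_effect=effect)
        assert abs(truth.implied_or("H-NS", "early", "never", "C>T") - 2.0) < 1e-12
        assert abs(truth.implied_or("H-NS", "early", "late", "C>T") - 4.0) < 1e-12


class TestSiteTable:
    def test_intercept_only_rate(self):
        cfg = sd.SiteTableConfig(n_sites=100_000, seed=1)
        table, _ = sd.simulate_site_table(cfg)
        p = 1 / (1 + np.exp(-cfg.intercept))
        se = np.sqrt(p * (1 - p) / len(table))
        assert abs(table.changed.mean() - p) <= 3 * se

    def test_binding_coefficient_recovered_by_logistic_fit(self):
        import statsmodels.api as sm

        coef = float(np.log(2))
        cfg = sd.SiteTableConfig(
            n_sites=100_000, coefficients={"cat_H-NS=early": coef}, seed=2
        )
        table, truth = sd.simulate_site_table(cfg)
        assert truth.logistic_coefficients["cat_H-NS=early"] == coef
        x = sm.add_constant((table["cat_H-NS"] == "early").astype(float))
        fit = sm.Logit(table.changed, x).fit(disp=0)
        est, se = fit.params.iloc[1], fit.bse.iloc[1]
        assert abs(est - coef) <= 3 * se

    def test_deterministic(self):
        cfg = sd.SiteTableConfig(n_sites=500, seed=7)
        a, _ = sd.simulate_site_table(cfg)
        b, _ = sd.simulate_site_table(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_excessive_probability_rejected(self):
        cfg = sd.SiteTableConfig(n_sites=100, intercept=1.0, seed=0)
        with pytest.raises(InvalidParameterError):
            sd.simulate_site_table(cfg)
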