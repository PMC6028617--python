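"""Ancestral reconstruction: model algebra, pruning oracles, gap logic."""

import itertools

import dendropy
import numpy as np
import pytest

from halo_adapt import asr
from halo_adapt import synthetic_data as sd

AA = asr.AMINO_ACIDS


def tree_from(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


class TestCprevModel:
    def test_normalised_to_one_substitution(self, cprev):
        q, pi = cprev.Q, cprev.frequencies
        assert -np.sum(pi * np.diag(q)) == pytest.approx(1.0, abs=1e-12)

    def test_detailed_balance(self, cprev):
        flux = cprev.frequencies[:, None] * cprev.Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_transition_matrix_stochastic(self, cprev, t):
        p = cprev.transition_matrix(t)
        assert p.min() >= 0.0
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_stationarity_of_pi(self, cprev):
        p = cprev.transition_matrix(3.0)
        np.testing.assert_allclose(cprev.frequencies @ p,
                                   cprev.frequencies, atol=1e-12)

    def test_corrupt_data_rejected(self):
        with pytest.raises(ValueError):
            asr.RateModel(exchangeabilities=np.ones((20, 20)),
                          frequencies=np.ones(20))  # does not sum to 1

    def test_discrete_gamma_rates_mean_one(self):
        rates = asr.discrete_gamma_rates(0.5, 4)
        assert rates.shape == (4,)
        assert np.all(np.diff(rates) > 0)
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)


class TestSiteLikelihood:
    def test_single_leaf_is_prior(self, cprev):
        tree = tree_from("(A:0.0);")
        for aa in "ARW":
            ll = asr.site_likelihood(tree, {"A": aa}, cprev)
            assert ll == pytest.approx(
                np.log(cprev.frequencies[AA.index(aa)]), abs=1e-12)

    def test_all_gap_column_likelihood_one(self, cprev):
        tree = tree_from("((A:0.1,B:0.2):0.1,C:0.3);")
        ll = asr.site_likelihood(tree, {"A": "-", "B": "-", "C": "-"}, cprev)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_enumeration(self, cprev):
        """Pruning equals the brute-force sum over internal states."""
        tree = tree_from("((A:0.12,B:0.3):0.15,C:0.25);")
        pi = cprev.frequencies
        p_a = cprev.transition_matrix(0.12)
        p_b = cprev.transition_matrix(0.3)
        p_u = cprev.transition_matrix(0.15)
        p_c = cprev.transition_matrix(0.25)
        states = {"A": AA.index("K"), "B": AA.index("E"), "C": AA.index("D")}
        total = 0.0
        for root, u in itertools.product(range(20), repeat=2):
            total += (pi[root] * p_u[root, u] * p_a[u, states["A"]]
                      * p_b[u, states["B"]] * p_c[root, states["C"]])
        ll = asr.site_likelihood(tree, {"A": "K", "B": "E", "C": "D"}, cprev)
        assert ll == pytest.approx(np.log(total), abs=1e-10)

    def test_taxon_mismatch_lists_difference(self, cprev):
        tree = tree_from("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="B.*C|C.*B"):
            asr.log_likelihood(tree, {"A": "K", "C": "R"}, cprev)

    def test_invariant_under_rerooting(self, cprev):
        aln = {"A": "KY", "B": "RY", "C": "D-", "D": "KV"}
        base = tree_from("((A:0.12,B:0.3):0.15,(C:0.08,D:0.4):0.2);")
        reference = asr.log_likelihood(base, aln, cprev)
        edges = [e for e in base.preorder_edge_iter() if e.length]
        for index in range(len(edges)):
            tree = tree_from(
                "((A:0.12,B:0.3):0.15,(C:0.08,D:0.4):0.2);")
            edge = [e for e in tree.preorder_edge_iter() if e.length][index]
            tree.reroot_at_edge(edge, length1=edge.length * 0.3,
                                length2=edge.length * 0.7)
            moved = asr.log_likelihood(tree, aln, cprev)
            np.testing.assert_allclose(moved, reference, atol=1e-10)


class TestMarginalPosteriors:
    def test_matches_joint_enumeration_four_leaves(self, cprev):
        tree = tree_from("((A:0.12,B:0.3):0.15,(C:0.08,D:0.4):0.2);")
        pi = cprev.frequencies
        p = {taxon: cprev.transition_matrix(t) for taxon, t in
             [("A", 0.12), ("B", 0.3), ("C", 0.08), ("D", 0.4)]}
        p_u, p_v = cprev.transition_matrix(0.15), cprev.transition_matrix(0.2)
        obs = {"A": AA.index("K"), "B": AA.index("R"),
               "C": AA.index("D"), "D": AA.index("K")}
        post_u = np.zeros(20)
        post_root = np.zeros(20)
        for r, u, v in itertools.product(range(20), repeat=3):
            term = (pi[r] * p_u[r, u] * p_v[r, v] * p["A"][u, obs["A"]]
                    * p["B"][u, obs["B"]] * p["C"][v, obs["C"]]
                    * p["D"][v, obs["D"]])
            post_u[u] += term
            post_root[r] += term
        post_u /= post_u.sum()
        post_root /= post_root.sum()
        aln = {"A": "K", "B": "R", "C": "D", "D": "K"}
        pp_u = asr.marginal_posteriors(tree, aln, cprev, {"A", "B"})[0]
        pp_root = asr.marginal_posteriors(tree, aln, cprev,
                                          tree.seed_node)[0]
        np.testing.assert_allclose(pp_u, post_u, atol=1e-10)
        np.testing.assert_allclose(pp_root, post_root, atol=1e-10)

    def test_zero_branch_to_leaf_clamps(self, cprev):
        tree = tree_from("((A:0.0,B:0.5):0.1,C:0.2);")
        pp = asr.marginal_posteriors(tree, {"A": "W", "B": "K", "C": "R"},
                                     cprev, {"A", "B"})[0]
        assert pp[AA.index("W")] == pytest.approx(1.0, abs=1e-12)

    def test_long_branch_star_approaches_prior(self, cprev):
        tree = tree_from("(A:60.0,B:60.0,C:60.0);")
        pp = asr.marginal_posteriors(tree, {"A": "K", "B": "K", "C": "K"},
                                     cprev, tree.seed_node)[0]
        np.testing.assert_allclose(pp, cprev.frequencies, atol=1e-4)

    def test_leaf_node_rejected(self, cprev):
        tree = tree_from("(A:0.1,B:0.1);")
        leaf = tree.leaf_nodes()[0]
        with pytest.raises(ValueError, match="leaf"):
            asr.marginal_posteriors(tree, {"A": "K", "B": "R"}, cprev, leaf)

    def test_posteriors_normalised(self, cprev):
        tree = sd.balanced_tree(8, 0.5)
        sim = sd.evolve_along_tree(sd.EvolutionSpec(
            tree=tree, root_length=50, indel_rate=0.05, seed=4))
        pp = asr.marginal_posteriors(sim.tree, sim.leaves, cprev,
                                     sim.tree.seed_node)
        np.testing.assert_allclose(pp.sum(axis=1), 1.0, atol=1e-9)
        assert pp.min() >= 0.0


class TestTreeAveraging:
    def test_identical_trees_equal_single(self, cprev):
        newick = "((A:0.1,B:0.1):0.05,C:0.2);"
        trees = [tree_from(newick) for _ in range(4)]
        aln = {"A": "K", "B": "R", "C": "E"}
        mean_pp, coverage = asr.average_over_trees(trees, aln, cprev,
                                                   {"A", "B"})
        single = asr.marginal_posteriors(trees[0], aln, cprev, {"A", "B"})
        np.testing.assert_allclose(mean_pp, single, atol=1e-12)
        assert coverage == 1.0

    def test_arithmetic_mean_of_two_trees(self, cprev):
        t1 = tree_from("((A:0.1,B:0.1):0.05,C:0.2);")
        t2 = tree_from("((A:0.4,B:0.02):0.1,C:0.1);")
        aln = {"A": "K", "B": "R", "C": "E"}
        pp1 = asr.marginal_posteriors(t1, aln, cprev, {"A", "B"})
        pp2 = asr.marginal_posteriors(t2, aln, cprev, {"A", "B"})
        mean_pp, _ = asr.average_over_trees([t1, t2], aln, cprev, {"A", "B"})
        np.testing.assert_allclose(mean_pp, (pp1 + pp2) / 2.0, atol=1e-12)

    def test_coverage_fraction_reported(self, cprev):
        with_clade = "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);"
        without = "((A:0.1,C:0.1):0.05,(B:0.1,D:0.1):0.05);"
        trees = [tree_from(with_clade)] * 3 + [tree_from(without)] * 2
        aln = {"A": "K", "B": "K", "C": "R", "D": "R"}
        _, coverage = asr.average_over_trees(trees, aln, cprev, {"A", "B"})
        assert coverage == pytest.approx(0.6)

    def test_absent_clade_is_error(self, cprev):
        trees = [tree_from("((A:0.1,C:0.1):0.05,(B:0.1,D:0.1):0.05);")]
        aln = {"A": "K", "B": "K", "C": "R", "D": "R"}
        with pytest.raises(ValueError):
            asr.average_over_trees(trees, aln, cprev, {"A", "B"})


class TestMcmcBookkeeping:
    def test_paper_style_burnin(self):
        spec = asr.McmcSampleSpec(n_generations=10_000_000,
                                  sample_frequency=1000, n_runs=2,
                                  burnin_fraction=0.4)
        # 2 × 10^7/1000 = 20,000 sampled; 40% burn-in leaves 12,000
        assert spec.n_runs * spec.n_generations // spec.sample_frequency \
            == 20_000
        assert asr.retained_samples(spec) == 12_000

    def test_zero_burnin_keeps_all(self):
        spec = asr.McmcSampleSpec(n_generations=5000, sample_frequency=10,
                                  burnin_fraction=0.0)
        assert asr.retained_samples(spec) == 500

    def test_non_divisible_floors(self):
        spec = asr.McmcSampleSpec(n_generations=1005, sample_frequency=10)
        assert asr.retained_samples(spec) == 100

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            asr.McmcSampleSpec(n_generations=0, sample_frequency=10)
        with pytest.raises(ValueError):
            asr.McmcSampleSpec(n_generations=10, sample_frequency=1,
                               burnin_fraction=1.0)


class TestGapCorrection:
    def test_no_gap_column_present(self):
        tree = tree_from("((A:0.1,B:0.1):0.1,C:0.1);")
        mask = asr.hall_gap_correction({"A": "K", "B": "R", "C": "E"},
                                       tree, tree.seed_node)
        assert mask.tolist() == [True]

    def test_all_gap_column_absent(self):
        tree = tree_from("((A:0.1,B:0.1):0.1,C:0.1);")
        mask = asr.hall_gap_correction({"A": "-", "B": "-", "C": "-"},
                                       tree, tree.seed_node)
        assert mask.tolist() == [False]

    def test_two_leaf_ambiguity_resolves_present(self):
        tree = tree_from("(A:0.1,B:0.1);")
        mask = asr.hall_gap_correction({"A": "K", "B": "-"},
                                       tree, tree.seed_node)
        assert mask.tolist() == [True]

    def test_gapped_subtree_inferred_absent(self):
        # both leaves of the target clade are gapped, the outgroup pair is
        # not: one loss above the clade beats two independent losses
        tree = tree_from("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = {"A": "-K", "B": "-K", "C": "EK", "D": "EK"}
        mask = asr.hall_gap_correction(aln, tree, {"A", "B"})
        assert mask.tolist() == [False, True]

    def test_never_absent_without_gaps(self, cprev):
        rng = np.random.default_rng(0)
        tree = sd.balanced_tree(8, 0.4)
        taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        aln = {t: "".join(rng.choice(list(AA), size=30)) for t in taxa}
        mask = asr.hall_gap_correction(aln, tree, tree.seed_node)
        assert mask.all()


class TestReconstruct:
    def test_single_column_identical_leaves(self, cprev):
        tree = tree_from("(A:0.1,B:0.1);")
        result = asr.reconstruct(tree, {"A": "W", "B": "W"},
                                 tree.seed_node, model=cprev)
        assert result.final_sequence == "W"
        assert result.presence_mask.tolist() == [True]

    def test_root_recovery_on_short_branch_simulation(self, cprev):
        """≥90% of simulated root states recovered on a 16-leaf tree of
        total depth 0.3 substitutions/site (200 sites)."""
        tree = sd.balanced_tree(16, 0.3)
        sim = sd.evolve_along_tree(sd.EvolutionSpec(
            tree=tree, root_length=200, seed=1))
        result = asr.reconstruct(sim.tree, sim.leaves, sim.tree.seed_node,
                                 model=cprev)
        truth = sim.internals[sim.root_label]
        recovery = np.mean([a == b for a, b in
                            zip(result.mpp_sequence, truth)])
        assert recovery >= 0.90

    def test_gapped_clade_columns_dropped(self, cprev):
        tree = tree_from("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = {"A": "-KE", "B": "-KE", "C": "RKE", "D": "RKE"}
        result = asr.reconstruct(tree, aln, {"A", "B"}, model=cprev)
        assert result.presence_mask.tolist() == [False, True, True]
        assert len(result.final_sequence) == 2

    def test_posterior_calibration_band(self, cprev):
        """Among sites with max-PP in [0.7, 0.8), the truth matches the
        call at a rate inside that band (3σ binomial tolerance)."""
        tree = sd.balanced_tree(8, 1.2)
        sim = sd.evolve_along_tree(sd.EvolutionSpec(
            tree=tree, root_length=4000, seed=11))
        result = asr.reconstruct(sim.tree, sim.leaves, sim.tree.seed_node,
                                 model=cprev)
        truth = sim.internals[sim.root_label]
        maxpp = result.max_pp()
        selected = np.flatnonzero((maxpp >= 0.7) & (maxpp < 0.8))
        assert len(selected) >= 100
        hits = np.mean([result.mpp_sequence[i] == truth[i]
                        for i in selected])
        sigma = np.sqrt(0.75 * 0.25 / len(selected))
        assert 0.7 - 3 * sigma <= hits <= 0.8 + 3 * sigma

    def test_mean_confidence_grows_as_branches_shrink(self, cprev):
        means = []
        for depth in (1.5, 0.5, 0.1):
            tree = sd.balanced_tree(8, depth)
            sim = sd.evolve_along_tree(sd.EvolutionSpec(
                tree=tree, root_length=400, seed=5))
            result = asr.reconstruct(sim.tree, sim.leaves,
                                     sim.tree.seed_node, model=cprev)
            means.append(result.max_pp().mean())
        assert means[0] < means[1] < means[2]

    def test_burnin_discards_leading_trees(self, cprev):
        good = "((A:0.1,B:0.1):0.05,C:0.2);"
        bad = "((A:2.9,B:2.9):0.05,C:0.2);"
        trees = [tree_from(bad)] * 2 + [tree_from(good)] * 3
        aln = {"A": "K", "B": "K", "C": "K"}
        with_burnin = asr.reconstruct(trees, aln, {"A", "B"}, model=cprev,
                                      burnin_fraction=0.4)
        reference = asr.marginal_posteriors(tree_from(good), aln, cprev,
                                            {"A", "B"})
        np.testing.assert_allclose(with_burnin.posteriors, reference,
                                   atol=1e-12)

    def test_lexicographic_tie_break(self):
        pp = np.zeros((1, 20))
        pp[0, AA.index("L")] = 0.5
        pp[0, AA.index("A")] = 0.5
        assert asr._mpp_sequence(pp) == "A"

    def test_pp_histogram_counts_retained_columns(self, cprev):
        tree = tree_from("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = {"A": "-KE", "B": "-KE", "C": "RKE", "D": "RKE"}
        result = asr.reconstruct(tree, aln, {"A", "B"}, model=cprev)
        counts, edges = result.pp_histogram()
        assert counts.sum() == 2  # absent column excluded
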