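"""Pruning engine: correctness against closed forms and brute force, and the
behaviour of branch-length / model optimisation."""

import numpy as np
import pytest

from genesignal import (
    Alignment,
    PruningEngine,
    SubstitutionModel,
    fit_model,
    optimize_branch_lengths,
    read_newick,
    simulate_alignment,
    site_log_likelihoods,
)
from genesignal.errors import GenesignalError
from conftest import random_alignment, random_model
from oracles import brute_force_site_lnl, jc_p_diff, jc_p_same


class TestSiteLikelihoods:
    def test_two_taxon_closed_form(self, jc1):
        tree = read_newick("(A:0.1,B:0.2);")
        aln = Alignment([("A", "AG"), ("B", "AC")])
        tab = site_log_likelihoods(aln, tree, jc1)
        t = 0.3  # path length between the two tips
        assert tab.per_site_lnL[0] == pytest.approx(np.log(0.25 * jc_p_same(t)), abs=1e-10)
        assert tab.per_site_lnL[1] == pytest.approx(np.log(0.25 * jc_p_diff(t)), abs=1e-10)

    def test_all_missing_column_has_zero_lnl(self, jc1):
        tree = read_newick("(A:0.1,B:0.2);")
        aln = Alignment([("A", "?"), ("B", "-")])
        tab = site_log_likelihoods(aln, tree, jc1)
        assert tab.per_site_lnL[0] == 0.0

    def test_matches_brute_force(self, quartet_tree, quartet_alignment):
        rng = np.random.default_rng(17)
        for _ in range(5):
            m = random_model(rng)
            mine = site_log_likelihoods(quartet_alignment, quartet_tree, m)
            ref = brute_force_site_lnl(quartet_alignment, quartet_tree, m)
            assert np.allclose(mine.per_site_lnL, ref, atol=1e-8)

    def test_missing_leaf_named_in_error(self, jc1):
        tree = read_newick("((A:1,B:1):1,C:1);")
        aln = Alignment([("A", "A"), ("B", "C")])
        with pytest.raises(GenesignalError, match="C"):
            site_log_likelihoods(aln, tree, jc1)

    def test_rerooting_invariance(self, gtr_model):
        rng = np.random.default_rng(2)
        tree = read_newick(
            "((A:0.1,B:0.3):0.2,(C:0.15,(D:0.2,E:0.1):0.15):0.1);"
        )
        aln = random_alignment(rng, list("ABCDE"), 30)
        base = site_log_likelihoods(aln, tree, gtr_model).per_site_lnL
        for leaf in "ABCDE":
            rerooted = tree.copy()
            rerooted.reroot_at_leaf(leaf)
            alt = site_log_likelihoods(aln, rerooted, gtr_model).per_site_lnL
            assert np.allclose(alt, base, atol=1e-8)

    def test_site_permutation_and_duplication(self, gtr_model, quartet_tree):
        rng = np.random.default_rng(8)
        aln = random_alignment(rng, list("ABCD"), 20)
        base = site_log_likelihoods(aln, quartet_tree, gtr_model).per_site_lnL
        order = rng.permutation(20)
        perm = Alignment(
            [(t, "".join(aln.row(t)[i] for i in order)) for t in aln.taxa]
        )
        out = site_log_likelihoods(perm, quartet_tree, gtr_model).per_site_lnL
        assert np.allclose(out, base[order], atol=1e-12)
        dup = Alignment([(t, aln.row(t) + aln.row(t)[0]) for t in aln.taxa])
        out2 = site_log_likelihoods(dup, quartet_tree, gtr_model)
        assert out2.per_site_lnL[-1] == pytest.approx(base[0], abs=1e-12)
        assert out2.total_lnL == pytest.approx(base.sum() + base[0], abs=1e-8)

    def test_table_invariants(self, gtr_model, quartet_tree):
        rng = np.random.default_rng(12)
        aln = random_alignment(rng, list("ABCD"), 25)
        tab = site_log_likelihoods(aln, quartet_tree, gtr_model)
        assert tab.n_sites == 25
        assert np.all(tab.per_site_lnL <= 0)
        assert tab.total_lnL == pytest.approx(tab.per_site_lnL.sum(), abs=1e-8)


class TestBranchOptimisation:
    def test_monotone_and_beats_truth(self, gtr_model):
        tree = read_newick(
            "((A:0.1,B:0.3):0.2,(C:0.15,(D:0.2,E:0.1):0.15):0.1);"
        )
        aln = simulate_alignment(tree, gtr_model, 1000, seed=3)
        at_truth = PruningEngine(aln, tree.copy(), gtr_model).total_log_likelihood()
        opt, info = optimize_branch_lengths(aln, tree, gtr_model)
        # the ML optimum dominates the generating lengths
        assert info.lnL >= at_truth - 1e-6

    def test_recovered_lengths_correlate_with_truth(self, gtr_model):
        tree = read_newick(
            "((A:0.05,B:0.3):0.1,(C:0.2,(D:0.4,E:0.08):0.15):0.12);"
        )
        aln = simulate_alignment(tree, gtr_model, 2000, seed=9)
        opt, _ = optimize_branch_lengths(aln, tree, gtr_model)
        true_tree = tree.copy()
        if true_tree.root_degree() == 2:
            true_tree.deroot()
        true_b = {}
        for node in true_tree.dtree.postorder_node_iter():
            if node.parent_node is not None:
                key = frozenset(l.taxon.label for l in node.leaf_iter())
                true_b[key] = node.edge.length
        est_b = {}
        for node in opt.dtree.postorder_node_iter():
            if node.parent_node is not None:
                key = frozenset(l.taxon.label for l in node.leaf_iter())
                est_b[key] = node.edge.length
        common = sorted(true_b, key=sorted)
        t = np.array([true_b[k] for k in common])
        e = np.array([est_b[k] for k in common])
        assert np.corrcoef(t, e)[0, 1] > 0.9

    def test_fixed_point_at_optimum(self, gtr_model):
        tree = read_newick("((A:0.1,B:0.3):0.2,(C:0.15,D:0.4):0.1);")
        aln = simulate_alignment(tree, gtr_model, 500, seed=4)
        once, info1 = optimize_branch_lengths(aln, tree, gtr_model, tol=1e-6)
        again, info2 = optimize_branch_lengths(aln, once, gtr_model, tol=1e-6)
        assert info2.lnL == pytest.approx(info1.lnL, abs=1e-4)
        assert info2.n_passes <= 2

    def test_never_decreases_from_random_starts(self, jc1):
        rng = np.random.default_rng(21)
        for _ in range(10):
            lengths = rng.uniform(0.01, 1.0, 6)
            nwk = (
                f"((A:{lengths[0]},B:{lengths[1]}):{lengths[4]},"
                f"(C:{lengths[2]},D:{lengths[3]}):{lengths[5]});"
            )
            tree = read_newick(nwk)
            aln = random_alignment(rng, list("ABCD"), 60, missing_frac=0.0)
            before = PruningEngine(aln, tree.copy(), jc1).total_log_likelihood()
            _, info = optimize_branch_lengths(aln, tree, jc1, tol=1e-5)
            assert info.lnL >= before - 1e-9


class TestModelFit:
    def test_refit_is_fixed_point(self, gtr_model):
        tree = read_newick("((A:0.1,B:0.3):0.2,(C:0.15,D:0.4):0.1);")
        aln = simulate_alignment(tree, gtr_model, 800, seed=6)
        m1, t1, r1 = fit_model(aln, tree)
        m2, t2, r2 = fit_model(
            aln, t1, gamma_shape=m1.gamma_shape, n_categories=m1.n_categories
        )
        assert r2.lnL >= r1.lnL - 1e-2

    def test_jc_data_gives_similar_exchangeabilities(self):
        jc4 = SubstitutionModel.jc(gamma_shape=1.0, n_categories=1)
        tree = read_newick(
            "((A:0.15,B:0.2):0.1,(C:0.25,(D:0.2,E:0.15):0.1):0.1);"
        )
        aln = simulate_alignment(tree, jc4, 5000, seed=13)
        m, _, _ = fit_model(aln, tree, n_categories=1)
        ex = np.asarray(m.exchangeabilities)
        assert ex.max() / ex.min() < 1.5
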