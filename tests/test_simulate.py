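"""Forward simulator, missingness masking, and the conflict-dataset generator."""

import numpy as np
import pytest

from genesignal import (
    GeneMap,
    GeneSpec,
    SimulationConfig,
    apply_missingness,
    build_topology_pair,
    default_config,
    generate_conflict_dataset,
    missingness_report,
    read_newick,
    simulate_alignment,
)
from genesignal.errors import GenesignalError
from oracles import jc_p_diff


class TestSimulateAlignment:
    def test_same_seed_identical(self, jc1):
        tree = read_newick("((A:0.1,B:0.2):0.1,(C:0.1,D:0.3):0.1);")
        a1 = simulate_alignment(tree, jc1, 200, seed=42)
        a2 = simulate_alignment(tree, jc1, 200, seed=42)
        assert a1 == a2
        assert a1 != simulate_alignment(tree, jc1, 200, seed=43)

    def test_base_frequencies_law_of_large_numbers(self, jc1):
        tree = read_newick("(A:0.05,B:0.05);")
        aln = simulate_alignment(tree, jc1, 100_000, seed=7)
        chars = np.concatenate([list(aln.row(t)) for t in aln.taxa])
        for b in "ACGT":
            freq = (chars == b).mean()
            assert 0.24 < freq < 0.26

    def test_pairwise_distance_matches_jc_expectation(self, jc1):
        for t in (0.05, 0.2, 0.5):
            tree = read_newick(f"(A:{t / 2},B:{t / 2});")
            n = 20_000
            aln = simulate_alignment(tree, jc1, n, seed=3)
            diff = np.mean(
                np.array(list(aln.row("A"))) != np.array(list(aln.row("B")))
            )
            expect = 3 * jc_p_diff(t)
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(diff - expect) < 3 * se

    def test_unlabelled_branch_lengths_rejected(self, jc1):
        with pytest.warns(UserWarning):
            tree = read_newick("((A,B),C);")  # lengths default to 0.0
        aln = simulate_alignment(tree, jc1, 10, seed=0)  # zero lengths are legal
        assert aln.row("A") == aln.row("B") == aln.row("C")


class TestApplyMissingness:
    def _aln_and_map(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(20)]
        rows = [(t, "".join(rng.choice(list("ACGT"), 50))) for t in taxa]
        gm = GeneMap.from_lengths([(f"g{i}", 10) for i in range(5)])
        from genesignal import Alignment

        return Alignment(rows), gm

    def test_zero_probability_is_identity(self):
        aln, gm = self._aln_and_map()
        assert apply_missingness(aln, gm, 0.0, seed=1) == aln

    def test_probability_one_always_fails(self):
        aln, gm = self._aln_and_map()
        with pytest.raises(GenesignalError, match="all taxa"):
            apply_missingness(aln, gm, 1.0, seed=1)

    def test_block_rate_within_binomial_bounds(self):
        aln, gm = self._aln_and_map()
        p = 0.3
        masked = apply_missingness(aln, gm, p, seed=5)
        blocks = 0
        for name, start, end in gm.entries:
            for t in masked.taxa:
                if masked.row(t)[start - 1 : end] == "?" * (end - start + 1):
                    blocks += 1
        n = len(gm.entries) * aln.n_taxa
        se = np.sqrt(p * (1 - p) * n)
        assert abs(blocks - p * n) < 4 * se

    def test_report_agrees_with_mask(self):
        aln, gm = self._aln_and_map()
        masked = apply_missingness(aln, gm, 0.4, seed=9)
        rep = missingness_report(masked, gm)
        for _, row in rep.iterrows():
            start, end = gm.range_of(row["gene"])
            frac = np.mean(
                [
                    masked.row(t)[start - 1 : end] == "?" * (end - start + 1)
                    for t in masked.taxa
                ]
            )
            assert row["missing_fraction"] == pytest.approx(frac)


class TestConflictDataset:
    def test_structure_and_truth_table(self):
        ds = generate_conflict_dataset(default_config(seed=2))
        assert len(ds.gene_alignments) == 5
        assert ds.genes.total_span == ds.supermatrix.length
        assert set(ds.truth_table["expected_sign"]) <= {-1, 0, 1}
        strong = ds.truth_table.set_index("gene").loc["rpb2_like"]
        assert strong["expected_sign"] == 1
        # the two skeletons differ by exactly the contested internode splits
        ab, ac = ds.tree_ab, ds.tree_ac
        assert ab.leaf_set == ac.leaf_set
        assert ab.bipartitions() != ac.bipartitions()

    def test_adding_a_gene_keeps_earlier_genes(self):
        cfg = default_config(seed=4)
        ds1 = generate_conflict_dataset(cfg)
        extra = SimulationConfig(
            clade_a=cfg.clade_a,
            clade_b=cfg.clade_b,
            clade_c=cfg.clade_c,
            outgroup=cfg.outgroup,
            gene_specs=cfg.gene_specs + (GeneSpec("new", 100, "AB"),),
            model=cfg.model,
            seed=4,
        )
        ds2 = generate_conflict_dataset(extra)
        for (n1, a1), (n2, a2) in zip(ds1.gene_alignments, ds2.gene_alignments):
            assert n1 == n2 and a1 == a2

    def test_missingness_flows_into_supermatrix(self):
        ds = generate_conflict_dataset(default_config(seed=6, missingness=0.5))
        rep = missingness_report(ds.supermatrix, ds.genes)
        # roughly half the blocks masked: binomial bounds per gene (n=12)
        assert np.all(rep["missing_fraction"] > 0.05)
        assert np.all(rep["missing_fraction"] < 0.95)
        assert np.all(rep["n_taxa_present"] >= 1)

    def test_internode_zero_marks_no_expected_signal(self):
        cfg = default_config(seed=1)
        cfg2 = SimulationConfig(
            clade_a=cfg.clade_a,
            clade_b=cfg.clade_b,
            clade_c=cfg.clade_c,
            outgroup=cfg.outgroup,
            gene_specs=(GeneSpec("flat", 200, "AB", internode_length=0.0),),
            model=cfg.model,
            seed=1,
        )
        ds = generate_conflict_dataset(cfg2)
        assert ds.truth_table.loc[0, "expected_sign"] == 0


class TestTopologyPair:
    def test_skeletons_realise_their_sisterhoods(self):
        cfg = default_config()
        ab, ac = build_topology_pair(cfg, internode_length=0.1)
        from genesignal import CladeConstraint, satisfies_constraint

        c_ab = CladeConstraint(frozenset(cfg.clade_a), frozenset(cfg.clade_b))
        c_ac = CladeConstraint(frozenset(cfg.clade_a), frozenset(cfg.clade_c))
        assert satisfies_constraint(ab, c_ab)
        assert not satisfies_constraint(ab, c_ac)
        assert satisfies_constraint(ac, c_ac)
        assert not satisfies_constraint(ac, c_ab)
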