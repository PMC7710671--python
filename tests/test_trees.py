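"""Newick round-trips, split extraction, monophyly, clade constraints,
constrained-tree construction and the NNI search."""

import numpy as np
import pytest

from genesignal import (
    CladeConstraint,
    build_constrained_tree,
    is_monophyletic,
    nni_search,
    read_newick,
    satisfies_constraint,
    simulate_alignment,
    write_newick,
)
from genesignal.errors import ConstraintError, NewickError
from oracles import tuple_splits, tuple_to_newick, unrooted_topologies


class TestNewick:
    def test_parse_basics(self):
        t = read_newick("((A:1,B:1):0.5,C:1);")
        assert sorted(t.leaf_labels()) == ["A", "B", "C"]
        inner = [
            n.edge.length
            for n in t.dtree.postorder_node_iter()
            if n.child_nodes() and n.parent_node is not None
        ]
        assert inner == [0.5]

    def test_roundtrip_preserves_splits_and_lengths(self):
        rng = np.random.default_rng(0)
        for topo in unrooted_topologies(list("ABCDEF")[:5])[:8]:
            nwk = tuple_to_newick(topo, brlen=float(rng.uniform(0.01, 2)))
            t = read_newick(nwk)
            again = read_newick(write_newick(t))
            assert again.bipartitions() == t.bipartitions()
            assert write_newick(again) == write_newick(t)

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(NewickError):
            read_newick("((A,B),(A,C));")

    def test_unbalanced_parens_rejected(self):
        with pytest.raises(NewickError):
            read_newick("((A:1,B:1):0.5,C:1;")

    def test_missing_lengths_warn_and_default(self):
        with pytest.warns(UserWarning, match="missing"):
            t = read_newick("((A,B),C);")
        assert all(
            n.edge.length == 0.0
            for n in t.dtree.postorder_node_iter()
            if n.parent_node is not None
        )


class TestMonophyly:
    def test_quartet_examples(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})

    def test_unknown_taxon_rejected(self):
        t = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ConstraintError, match="Z"):
            is_monophyletic(t, {"A", "Z"})

    def test_exhaustive_five_leaf_oracle(self):
        import itertools

        labels = list("ABCDE")
        topos = unrooted_topologies(labels)
        assert len(topos) == 15
        seen = set()
        for topo in topos:
            splits = tuple_splits(topo)
            seen.add(frozenset(splits))
            t = read_newick(tuple_to_newick(topo))
            assert t.bipartitions() == splits
            for r in range(2, 4):
                for taxa in itertools.combinations(labels, r):
                    side = frozenset(taxa)
                    ref = min(labels)
                    norm = (
                        frozenset(labels) - side if ref in side else side
                    )
                    expected = (
                        len(norm) < 2 or len(norm) > 3 or norm in splits
                    )
                    assert is_monophyletic(t, side) == expected, (topo, taxa)
        assert len(seen) == 15  # all topologies distinct


class TestConstraint:
    def test_satisfied_and_violated(self):
        t = read_newick("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);")
        c = CladeConstraint(frozenset("CD"), frozenset("EF"))
        assert satisfies_constraint(t, c)
        # with 6 leaves, {C,D,E,F} is the complement of the {A,B} cherry and
        # hence still a split; 8 leaves are needed for a genuine violation
        t2 = read_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        )
        assert not satisfies_constraint(t2, c)

    def test_overlapping_clades_rejected(self):
        with pytest.raises(ConstraintError, match="overlap"):
            CladeConstraint(frozenset("AB"), frozenset("BC"))


class TestBuildConstrainedTree:
    NWK = (
        "(((A1:0.1,A2:0.1):0.1,(B1:0.1,B2:0.1):0.1):0.1,"
        "((C1:0.1,C2:0.1):0.1,(O1:0.1,O2:0.1):0.1):0.1);"
    )

    def test_regraft_makes_sisters(self):
        t1 = read_newick(self.NWK)
        c = CladeConstraint(frozenset(["A1", "A2"]), frozenset(["C1", "C2"]))
        t2 = build_constrained_tree(t1, c)
        assert satisfies_constraint(t2, c)
        assert t2.leaf_set == t1.leaf_set
        assert t2.n_edges() == t1.n_edges()
        # the new union split is an edge of T2
        union = t2._normalize(frozenset(["A1", "A2", "C1", "C2"]))
        assert union in t2.bipartitions()

    def test_already_satisfied_returns_copy(self):
        t1 = read_newick(self.NWK)
        c = CladeConstraint(frozenset(["A1", "A2"]), frozenset(["B1", "B2"]))
        t2 = build_constrained_tree(t1, c)
        assert t2.bipartitions() == t1.bipartitions()

    def test_paraphyletic_clade_rejected(self):
        t1 = read_newick(self.NWK)
        c = CladeConstraint(frozenset(["A1", "B1"]), frozenset(["C1", "C2"]))
        with pytest.raises(ConstraintError, match="clade_x"):
            build_constrained_tree(t1, c)

    def test_split_sets_differ_only_at_contested_edges(self):
        t1 = read_newick(self.NWK)
        c = CladeConstraint(frozenset(["A1", "A2"]), frozenset(["C1", "C2"]))
        t2 = build_constrained_tree(t1, c)
        gained = t2.bipartitions() - t1.bipartitions()
        lost = t1.bipartitions() - t2.bipartitions()
        # every changed split involves the moved clade on one side
        for s in gained | lost:
            side = set(s)
            comp = t1.leaf_set - side
            assert {"C1", "C2"} <= side or {"C1", "C2"} <= comp


class TestNNISearch:
    TRUE = (
        "(((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.1,"
        "((E:0.1,F:0.1):0.1,(G:0.1,H:0.1):0.1):0.1);"
    )
    START = (
        "(((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1):0.1,"
        "((E:0.1,F:0.1):0.1,(G:0.1,H:0.1):0.1):0.1);"
    )

    def test_local_optimum_is_fixed_point(self, jc1):
        true_tree = read_newick(self.TRUE)
        aln = simulate_alignment(true_tree, jc1, 800, seed=1)
        out = nni_search(aln, true_tree, jc1)
        assert out.bipartitions() == true_tree.bipartitions()

    def test_recovers_from_one_move_away(self, jc1):
        true_tree = read_newick(self.TRUE)
        aln = simulate_alignment(true_tree, jc1, 1000, seed=2)
        out = nni_search(aln, read_newick(self.START), jc1)
        assert out.bipartitions() == true_tree.bipartitions()

    def test_constraint_always_respected(self, jc1):
        true_tree = read_newick(self.TRUE)
        con = CladeConstraint(frozenset("AB"), frozenset("CD"))
        aln = simulate_alignment(true_tree, jc1, 400, seed=3)
        start = read_newick(self.TRUE)
        out = nni_search(aln, start, jc1, constraint=con)
        assert satisfies_constraint(out, con)

    def test_violating_start_rejected(self, jc1):
        aln = simulate_alignment(read_newick(self.TRUE), jc1, 100, seed=4)
        con = CladeConstraint(frozenset("AC"), frozenset("BD"))
        with pytest.raises(ConstraintError, match="violates"):
            nni_search(aln, read_newick(self.TRUE), jc1, constraint=con)
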