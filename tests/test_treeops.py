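import itertools

import numpy as np
import pytest

from hgtest.models import two_state_model
from hgtest.phylik import total_log_likelihood
from hgtest.seqsim import random_species_tree, simulate_alignment
from hgtest.treeops import (MonophylyConstraint, NewickError, PhyloTree,
                            constrained_start_tree, count_unrooted_topologies,
                            enumerate_topologies, is_compatible, nni_neighbors,
                            parse_newick, rf_distance, search_ml_tree,
                            spr_transfer, write_newick)
from _oracles import dendropy_rf


class TestNewick:
    def test_basic_quartet(self):
        t = parse_newick("(A:0.1,B:0.2,(C:0.3,D:0.4):0.5);")
        assert t.n_leaves == 4
        internal = [n for n in t.edges() if not n.is_leaf]
        assert len(internal) == 1 and internal[0].length == pytest.approx(0.5)

    def test_rooted_input_is_unrooted(self):
        a = parse_newick("((A:1,B:1):0.25,(C:1,D:1):0.25);")
        b = parse_newick("(A:1,B:1,(C:1,D:1):0.5);")
        assert a.same_topology(b)
        assert rf_distance(a, b) == 0

    def test_round_trip_random_trees(self):
        for seed in range(30):
            t = random_species_tree(4 + seed % 6, seed)
            back = parse_newick(write_newick(t))
            assert back.splits() == t.splits()
            lengths = sorted(n.length for n in t.edges())
            lengths2 = sorted(n.length for n in back.edges())
            assert np.allclose(lengths, lengths2, rtol=1e-9)

    def test_quoted_labels(self):
        t = parse_newick("('sp one':0.1,'sp two':0.2,'it''s':0.3);")
        assert t.leaf_labels() == {"sp one", "sp two", "it's"}
        assert parse_newick(t.to_newick()).leaf_labels() == t.leaf_labels()

    def test_duplicate_label_rejected(self):
        with pytest.raises(NewickError, match="duplicate"):
            parse_newick("(A,A);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("((A,B,(C,D);")


class TestConstraints:
    TREE = parse_newick("((A,B),(C,D));")

    def test_cherry_is_compatible(self):
        assert is_compatible(self.TREE, MonophylyConstraint([{"A", "B"}]))

    def test_split_pair_is_not(self):
        assert not is_compatible(self.TREE, MonophylyConstraint([{"A", "C"}]))

    def test_whole_leaf_set_trivially_true(self):
        assert is_compatible(self.TREE,
                             MonophylyConstraint([{"A", "B", "C", "D"}]))

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="Z"):
            is_compatible(self.TREE, MonophylyConstraint([{"A", "Z"}]))

    def test_overlapping_groups_must_nest(self):
        MonophylyConstraint([{"A", "B", "C"}, {"A", "B"}])  # nested: fine
        with pytest.raises(ValueError, match="nested"):
            MonophylyConstraint([{"A", "B"}, {"B", "C"}])

    def test_start_tree_respects_nested_groups(self):
        c = MonophylyConstraint([{"A", "B", "C"}, {"A", "B"}, {"E", "F"}])
        t = constrained_start_tree("ABCDEF", c)
        assert is_compatible(t, c)
        assert t.n_leaves == 6


class TestEnumeration:
    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_topology_count_is_double_factorial(self, n):
        labels = [f"t{i}" for i in range(n)]
        topos = enumerate_topologies(labels)
        assert len(topos) == count_unrooted_topologies(n)
        # all distinct as unrooted topologies
        assert len({t.splits() for t in topos}) == len(topos)

    def test_constraint_filter_matches_collapsed_closed_form(self):
        # collapsing a constrained cherry leaves an unrooted 4-taxon problem
        topos = enumerate_topologies("ABCDE")
        c = MonophylyConstraint([{"A", "B"}])
        compatible = [t for t in topos if is_compatible(t, c)]
        assert len(topos) == 15
        assert len(compatible) == 3

    @pytest.mark.parametrize("group", [{"A", "B"}, {"A", "B", "C"},
                                       {"D", "E", "F"}])
    def test_constraint_count_matches_pseudo_leaf_collapse(self, group):
        # collapsing a constrained group to one pseudo-leaf must leave
        # (2m-5)!! x (2k-5)!! topologies: shapes inside the group times
        # shapes of the collapsed problem
        labels = list("ABCDEF")
        topos = enumerate_topologies(labels)
        c = MonophylyConstraint([group])
        n_compatible = sum(is_compatible(t, c) for t in topos)
        k = len(labels) - len(group) + 1  # collapsed problem size
        inside = count_unrooted_topologies(len(group) + 1)  # rooted shapes
        outside = count_unrooted_topologies(k) if k >= 3 else 1
        assert n_compatible == inside * outside

    def test_nni_neighborhood_size_and_distance(self):
        t = random_species_tree(6, 3)
        nbrs = nni_neighbors(t)
        assert len(nbrs) == 2 * (6 - 3)
        for nb in nbrs:
            assert rf_distance(t, nb) == 2
        # neighbors are pairwise distinct topologies
        assert len({nb.splits() for nb in nbrs}) == len(nbrs)

    def test_nni_neighborhood_is_symmetric(self):
        t = random_species_tree(5, 7)
        for nb in nni_neighbors(t):
            back = {x.splits() for x in nni_neighbors(nb)}
            assert t.splits() in back


class TestSPR:
    def test_regraft_to_original_edge_is_identity(self):
        # E already sits on the edge subtending (C,D): re-attaching it
        # there must not change the unrooted topology
        t = parse_newick("(F:1,(A:1,B:1):1,(E:1,(C:1,D:1):1):1);")
        moved = spr_transfer(t, {"C", "D"}, "E")
        assert rf_distance(t, moved) == 0

    def test_transfer_creates_required_clade(self):
        t = random_species_tree(7, 21)
        donor = next(n.leaf_labels() for n in t.postorder()
                     if n.parent is not None and not n.is_leaf)
        recipient = sorted(t.leaf_labels() - donor)[0]
        moved = spr_transfer(t, donor, recipient)
        assert moved.leaf_labels() == t.leaf_labels()
        assert is_compatible(moved,
                             MonophylyConstraint([donor | {recipient}]))

    def test_rf_matches_dendropy_oracle(self):
        for seed in range(10):
            t1 = random_species_tree(8, seed)
            t2 = random_species_tree(8, 1000 + seed)
            ours = rf_distance(t1, t2)
            theirs = dendropy_rf(t1.to_newick(), t2.to_newick())
            assert ours == theirs
            assert ours == rf_distance(t2, t1)

    def test_identical_trees_distance_zero(self):
        t = random_species_tree(6, 2)
        assert rf_distance(t, t.copy()) == 0

    def test_quartet_topologies_distance_two(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));")
        assert rf_distance(a, b) == 2

    def test_leaf_set_mismatch_raises(self):
        a = parse_newick("(A,B,(C,D));")
        b = parse_newick("(A,B,(C,E));")
        with pytest.raises(ValueError, match="leaf sets"):
            rf_distance(a, b)

    def test_non_clade_donor_rejected(self):
        t = parse_newick("((A,B),(C,D),E);")
        with pytest.raises(ValueError, match="clade"):
            spr_transfer(t, {"A", "C"}, "E")

    def test_recipient_inside_donor_rejected(self):
        t = parse_newick("((A,B),(C,D),E);")
        with pytest.raises(ValueError, match="recipient"):
            spr_transfer(t, {"A", "B"}, "A")


@pytest.fixture(scope="module")
def quintet():
    model = two_state_model()
    tree = parse_newick("((A:0.3,B:0.3):0.25,(C:0.3,D:0.3):0.25,E:0.5);")
    aln = simulate_alignment(tree, model, 400, 17)
    return aln, model, tree


class TestSearch:
    def test_exhaustive_recovers_generating_topology(self, quintet):
        aln, model, truth = quintet
        best, lnl = search_ml_tree(aln, model, None, mode="exhaustive")
        assert rf_distance(best, truth) == 0
        assert np.isfinite(lnl)

    def test_constraint_never_improves_likelihood(self, quintet):
        aln, model, _ = quintet
        _, free = search_ml_tree(aln, model, None, mode="exhaustive")
        c = MonophylyConstraint([{"A", "C"}])  # false constraint
        _, constrained = search_ml_tree(aln, model, c, mode="exhaustive")
        assert constrained <= free + 1e-6

    def test_all_taxa_constraint_equals_unconstrained(self, quintet):
        aln, model, _ = quintet
        c = MonophylyConstraint([set(aln.taxa)])
        t1, l1 = search_ml_tree(aln, model, None, mode="exhaustive")
        t2, l2 = search_ml_tree(aln, model, c, mode="exhaustive")
        assert rf_distance(t1, t2) == 0
        assert l1 == pytest.approx(l2, abs=1e-6)

    def test_exhaustive_refuses_large_trees(self, lg_model):
        from hgtest.phylik import ProteinAlignment
        recs = [(f"t{i}", "A") for i in range(9)]
        aln = ProteinAlignment.from_records(recs)
        with pytest.raises(ValueError, match="nni"):
            search_ml_tree(aln, lg_model, None, mode="exhaustive")

    def test_nni_reaches_exhaustive_optimum(self, model4):
        # 4-state fixture with moderate lengths: branch lengths stay
        # identifiable (a saturated binary model has likelihood ridges)
        model = model4
        truth = random_species_tree(6, 99, branch_mean=0.2)
        aln = simulate_alignment(truth, model, 300, 5)
        _, best_lnl = search_ml_tree(aln, model, None, mode="exhaustive")
        hits = 0
        n_starts = 20
        for s in range(n_starts):
            start = random_species_tree(6, 5000 + s,
                                        labels=sorted(aln.taxa))
            _, lnl = search_ml_tree(aln, model, None, mode="nni",
                                    start_tree=start)
            if lnl >= best_lnl - 0.01:
                hits += 1
        assert hits >= 0.95 * n_starts
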