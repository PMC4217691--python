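import numpy as np
import pytest

from hgtest.models import two_state_model
from hgtest.phylik import (ProteinAlignment, SiteLLMatrix,
                           optimize_branch_lengths, site_ll_matrix,
                           site_log_likelihoods, total_log_likelihood)
from hgtest.seqsim import random_species_tree, simulate_alignment
from hgtest.treeops import enumerate_topologies, parse_newick
from _oracles import brute_force_site_lls


def _random_alignment(rng, taxa, n_sites, alphabet, missing_rate=0.15):
    codes = rng.integers(0, len(alphabet), size=(len(taxa), n_sites))
    mask = rng.random(codes.shape) < missing_rate
    codes[mask] = -1
    return ProteinAlignment(list(taxa), codes.astype(np.int16), alphabet)


class TestPruningOracle:
    @pytest.mark.parametrize("n_taxa", [3, 4])
    @pytest.mark.parametrize("which_model", ["model2", "model4"])
    def test_matches_exhaustive_enumeration(self, n_taxa, which_model, request):
        model = request.getfixturevalue(which_model)
        rng = np.random.default_rng(n_taxa * 7 + len(model.states))
        taxa = [chr(65 + i) for i in range(n_taxa)]
        for topo in enumerate_topologies(taxa):
            t = topo.copy()
            for e in t.edges():
                e.length = float(rng.uniform(0.0, 1.0))
            aln = _random_alignment(rng, taxa, 3, model.states)
            ours = site_log_likelihoods(aln, t, model)
            oracle = brute_force_site_lls(aln, t, model)
            assert np.allclose(ours, oracle, atol=1e-10)

    def test_gamma_and_invariant_categories(self, request):
        base = request.getfixturevalue("model4")
        model = base.with_rates(alpha=0.6, p_inv=0.2, n_cat=3)
        rng = np.random.default_rng(12)
        taxa = list("ABCD")
        t = parse_newick("((A:0.2,B:0.4):0.15,C:0.3,D:0.6);")
        aln = _random_alignment(rng, taxa, 3, model.states)
        assert np.allclose(site_log_likelihoods(aln, t, model),
                           brute_force_site_lls(aln, t, model), atol=1e-10)

    def test_zero_length_identical_residue(self, model2):
        t = parse_newick("(A:0,B:0);")
        aln = ProteinAlignment.from_records([("A", "0"), ("B", "0")], "01")
        ll = site_log_likelihoods(aln, t, model2)
        assert ll[0] == pytest.approx(np.log(model2.frequencies[0]), abs=1e-12)

    def test_zero_length_conflict_is_minus_inf(self, model2):
        t = parse_newick("(A:0,B:0);")
        aln = ProteinAlignment.from_records([("A", "0"), ("B", "1")], "01")
        assert np.isneginf(site_log_likelihoods(aln, t, model2)[0])

    def test_rerooting_invariance(self, model4):
        import dendropy
        rng = np.random.default_rng(4)
        tree = random_species_tree(6, 8)
        aln = _random_alignment(rng, sorted(tree.leaf_labels()), 20,
                                model4.states)
        ref = site_log_likelihoods(aln, tree, model4)
        nwk = tree.to_newick()
        for k in range(4):
            dt = dendropy.Tree.get(data=nwk, schema="newick",
                                   preserve_underscores=True)
            internals = [n for n in dt.preorder_node_iter()
                         if not n.is_leaf()]
            dt.reroot_at_node(internals[k], update_bipartitions=False)
            rerooted = parse_newick(dt.as_string(schema="newick"))
            assert np.allclose(site_log_likelihoods(aln, rerooted, model4),
                               ref, atol=1e-9)

    def test_leaf_set_mismatch_lists_difference(self, model2):
        t = parse_newick("(A:0.1,B:0.1,C:0.1);")
        aln = ProteinAlignment.from_records(
            [("A", "0"), ("B", "1"), ("D", "0")], "01")
        with pytest.raises(ValueError, match="C.*D|D.*C"):
            site_log_likelihoods(aln, t, model2)


class TestTotals:
    def test_repeated_pattern_scales_linearly(self, model4):
        t = parse_newick("((A:0.2,B:0.3):0.1,C:0.4,D:0.2);")
        one = ProteinAlignment.from_records(
            [("A", "A"), ("B", "C"), ("C", "G"), ("D", "A")], "ACGT")
        hundred = ProteinAlignment.from_records(
            [(l, s * 100) for l, s in one.records()], "ACGT")
        assert total_log_likelihood(hundred, t, model4) == pytest.approx(
            100 * total_log_likelihood(one, t, model4), abs=1e-9)

    def test_total_equals_sum_of_site_lls(self, model4):
        rng = np.random.default_rng(3)
        tree = random_species_tree(5, 13)
        aln = _random_alignment(rng, sorted(tree.leaf_labels()), 200,
                                model4.states)
        assert total_log_likelihood(aln, tree, model4) == pytest.approx(
            float(site_log_likelihoods(aln, tree, model4).sum()), abs=1e-9)

    def test_all_gap_column_contributes_zero(self, model4):
        t = parse_newick("((A:0.2,B:0.3):0.1,C:0.4,D:0.2);")
        base = ProteinAlignment.from_records(
            [("A", "AC"), ("B", "CC"), ("C", "GT"), ("D", "AA")], "ACGT")
        padded = ProteinAlignment.from_records(
            [(l, s + "-") for l, s in base.records()], "ACGT")
        assert total_log_likelihood(padded, t, model4) == pytest.approx(
            total_log_likelihood(base, t, model4), abs=1e-12)
        assert site_log_likelihoods(padded, t, model4)[-1] == pytest.approx(0.0)

    def test_all_missing_taxon_on_zero_pendant_is_neutral(self, model4):
        rng = np.random.default_rng(9)
        base_tree = parse_newick("((A:0.2,B:0.3):0.1,C:0.4,D:0.2);")
        # same tree with the 0.1 edge split in half and a missing taxon
        # hanging off the midpoint on a zero-length pendant edge
        aug_tree = parse_newick(
            "(((A:0.2,B:0.3):0.05,X:0):0.05,C:0.4,D:0.2);")
        aln = _random_alignment(rng, list("ABCD"), 30, model4.states)
        aug = ProteinAlignment(
            aln.taxa + ["X"],
            np.vstack([aln.codes, np.full((1, 30), -1, dtype=np.int16)]),
            model4.states)
        assert total_log_likelihood(aug, aug_tree, model4) == pytest.approx(
            total_log_likelihood(aln, base_tree, model4), abs=1e-9)


class TestOptimization:
    def test_two_taxon_closed_form(self, model2):
        tree = parse_newick("(A:0.05,B:0.05);")
        aln = simulate_alignment(tree, model2, 4000, 11)
        d = float((aln.codes[0] != aln.codes[1]).mean())
        expected = -0.5 * np.log(1 - 2 * d)
        opt, _ = optimize_branch_lengths(aln, tree, model2, tol=1e-10,
                                         max_rounds=40, xatol=1e-9)
        total = sum(e.length for e in opt.edges())
        assert total == pytest.approx(expected, abs=1e-4)

    def test_fixed_point_at_optimum(self, model2):
        tree = parse_newick("(A:0.1,B:0.2,(C:0.15,D:0.3):0.1);")
        aln = simulate_alignment(tree, model2, 500, 2)
        opt, lnl1 = optimize_branch_lengths(aln, tree, model2, tol=1e-8,
                                            max_rounds=30, xatol=1e-8)
        _, lnl2 = optimize_branch_lengths(aln, opt, model2, tol=1e-8,
                                          max_rounds=1, xatol=1e-8)
        assert lnl2 - lnl1 < 1e-4
        assert lnl2 >= lnl1 - 1e-9

    def test_restarts_reach_same_optimum(self, model4):
        truth = random_species_tree(5, 31, branch_mean=0.3)
        aln = simulate_alignment(truth, model4, 300, 7)
        rng = np.random.default_rng(0)
        finals = []
        for _ in range(3):
            start = truth.copy()
            for e in start.edges():
                e.length = float(rng.uniform(0.01, 1.0))
            _, lnl = optimize_branch_lengths(aln, start, model4, tol=1e-9,
                                             max_rounds=60, xatol=1e-9)
            finals.append(lnl)
        assert max(finals) - min(finals) < 1e-6


class TestSiteLLMatrix:
    def test_identical_trees_identical_rows(self, model4):
        tree = random_species_tree(5, 1)
        aln = simulate_alignment(tree, model4, 100, 3)
        m = site_ll_matrix(aln, [tree, tree.copy()], model4, optimize=False)
        assert np.array_equal(m.values[0], m.values[1])

    def test_row_sum_equals_total(self, model4):
        tree = random_species_tree(5, 1)
        aln = simulate_alignment(tree, model4, 100, 3)
        m = site_ll_matrix(aln, [tree], model4, optimize=False)
        assert m.totals()[0] == pytest.approx(
            total_log_likelihood(aln, tree, model4), abs=1e-9)

    def test_duplicate_ids_rejected(self, model4):
        tree = random_species_tree(4, 1)
        aln = simulate_alignment(tree, model4, 10, 3)
        with pytest.raises(ValueError, match="duplicate"):
            site_ll_matrix(aln, [tree, tree], model4, tree_ids=["x", "x"])

    def test_tsv_round_trip(self, tmp_path, model4):
        tree = random_species_tree(4, 6)
        aln = simulate_alignment(tree, model4, 25, 3)
        m = site_ll_matrix(aln, [tree], model4, optimize=False,
                           tree_ids=["best"])
        path = tmp_path / "sitell.tsv"
        m.to_tsv(path)
        back = SiteLLMatrix.from_tsv(path)
        assert back.tree_ids == ["best"]
        assert np.allclose(back.values, m.values, atol=1e-9)

    def test_sitelh_two_line_variant(self, tmp_path):
        path = tmp_path / "x.sitelh"
        path.write_text("2 3\ntree1 -1.5 -2.5 -3.5\ntree2 -1 -2 -3\n")
        m = SiteLLMatrix.from_tsv(path)
        assert m.n_trees == 2 and m.n_sites == 3
        assert m.totals()[1] == pytest.approx(-6.0)
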