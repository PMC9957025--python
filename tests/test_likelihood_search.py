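import dendropy
import numpy as np
import pytest

from inteinscan import validation
from inteinscan.phylocore import (LeafDataMismatchError, ml_pairwise_distance,
                                  ml_search, optimize_branch_lengths,
                                  tree_log_likelihood, forms_clan,
                                  constrained_nj_tree, patristic_distances,
                                  nj_tree, distance_matrix)
from inteinscan.phylocore.models import AA_INDEX, AA_ORDER
from inteinscan.simgen import evolve_sequences, simulate_host_tree


class TestTreeLikelihood:
    def test_two_taxon_one_site_closed_form(self, wag_g4):
        t = 0.37
        tree = dendropy.Tree.get(data="(A:0.20,B:0.17);", schema="newick")
        _, per_site = tree_log_likelihood(tree, {"A": "M", "B": "K"}, wag_g4)
        P = wag_g4.transition_matrices(t)
        w = wag_g4.category_weights
        pi = wag_g4.frequencies
        a, b = AA_INDEX["M"], AA_INDEX["K"]
        expected = np.log(sum(w[c] * pi[a] * P[c, a, b] for c in range(len(w))))
        assert per_site[0] == pytest.approx(expected, abs=1e-10)

    def test_all_gap_column_contributes_zero(self, wag_g4):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.2);", schema="newick")
        _, per_site = tree_log_likelihood(tree, {"A": "M-", "B": "K-"}, wag_g4)
        assert per_site[1] == pytest.approx(0.0, abs=1e-12)

    def test_rerooting_invariance(self, wag_g4, rng):
        tree = dendropy.Tree.get(
            data="((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07,E:0.4);", schema="newick")
        seqs = {lf.taxon.label: "".join(rng.choice(list(AA_ORDER), 60))
                for lf in tree.leaf_node_iter()}
        l1, _ = tree_log_likelihood(tree, seqs, wag_g4)
        t2 = tree.clone(depth=1)
        internal = [nd for nd in t2.preorder_node_iter()
                    if not nd.is_leaf() and nd is not t2.seed_node]
        t2.reroot_at_node(internal[0], update_bipartitions=False)
        l2, _ = tree_log_likelihood(t2, seqs, wag_g4)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_leaf_data_mismatch_names_difference(self, wag_g4):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.2);", schema="newick")
        with pytest.raises(LeafDataMismatchError, match="B"):
            tree_log_likelihood(tree, {"A": "M", "C": "K"}, wag_g4)


class TestBranchLengthOptimization:
    def test_never_decreases_and_idempotent(self, wag_g4):
        host = simulate_host_tree(6, 1.0, 2)
        seqs = evolve_sequences(host, wag_g4, 120, seed=3)
        start = host.clone(depth=1)
        for nd in start.preorder_node_iter():
            if nd is not start.seed_node:
                nd.edge.length = 0.5
        before, _ = tree_log_likelihood(start, seqs, wag_g4)
        opt, after = optimize_branch_lengths(start, seqs, wag_g4, tol=1e-4)
        assert after >= before
        _, again = optimize_branch_lengths(opt, seqs, wag_g4, tol=1e-4)
        assert again - after < 1e-3

    def test_two_taxon_optimum_equals_pairwise_distance(self, wag_g4):
        host = simulate_host_tree(4, 1.0, 8)
        seqs4 = evolve_sequences(host, wag_g4, 300, seed=4)
        names = sorted(seqs4)[:2]
        seqs = {n: seqs4[n] for n in names}
        tree = dendropy.Tree.get(data=f"({names[0]}:0.2,{names[1]}:0.2);",
                                 schema="newick", preserve_underscores=True)
        opt, _ = optimize_branch_lengths(tree, seqs, wag_g4, tol=1e-8)
        total = sum(nd.edge.length for nd in opt.preorder_node_iter()
                    if nd is not opt.seed_node)
        d = ml_pairwise_distance(seqs[names[0]], seqs[names[1]], wag_g4)
        assert total == pytest.approx(d, abs=1e-4)


@pytest.fixture(scope="module")
def data8(wag_g4):
    host = simulate_host_tree(8, 1.0, 31, rooted=True)
    return evolve_sequences(host, wag_g4, 200, seed=32)


class TestMLSearch:
    def test_trivial_constraint_equals_unconstrained(self, wag_g4, data8):
        t_un, l_un = ml_search(data8, wag_g4, seed=0)
        t_all, l_all = ml_search(data8, wag_g4, seed=0, constraint=set(data8))
        assert l_all == pytest.approx(l_un, abs=1e-6)

    def test_constrained_tree_satisfies_clan_and_is_dominated(self, wag_g4, data8):
        clan = set(sorted(data8)[:4])
        t_un, l_un = ml_search(data8, wag_g4, seed=0)
        t_c, l_c = ml_search(data8, wag_g4, seed=0, constraint=clan)
        assert forms_clan(t_c, clan)
        assert l_c <= l_un + 1e-6

    def test_constrained_start_tree_respects_clans(self, wag_g4, data8):
        dm = distance_matrix(data8, wag_g4)
        taxa = sorted(data8)
        clans = [set(taxa[:3]), set(taxa[3:6])]
        start = constrained_nj_tree(dm, clans)
        for c in clans:
            assert forms_clan(start, c)
        assert {lf.taxon.label for lf in start.leaf_node_iter()} == set(taxa)

    def test_search_matches_exhaustive_on_six_taxa(self):
        res = validation.search_vs_exhaustive(seed=3)
        assert res["abs_diff"] < 1e-6

    def test_constraint_outside_taxa_rejected(self, wag_g4, data8):
        with pytest.raises(ValueError, match="ghost"):
            ml_search(data8, wag_g4, constraint={"ghost", *list(data8)[:2]})


def test_bootstrap_support_range_and_determinism(wag_g4):
    from inteinscan.phylocore import bootstrap_support
    from inteinscan.alnio import Alignment
    host = simulate_host_tree(6, 1.0, 13, rooted=True)
    seqs = evolve_sequences(host, wag_g4, 150, seed=14)
    aln = Alignment(ids=sorted(seqs), rows=seqs)
    t1 = bootstrap_support(aln, wag_g4, n_reps=100, seed=5)
    t2 = bootstrap_support(aln, wag_g4, n_reps=100, seed=5)
    sup1 = sorted(float(nd.label) for nd in t1.postorder_node_iter()
                  if nd.label is not None)
    sup2 = sorted(float(nd.label) for nd in t2.postorder_node_iter()
                  if nd.label is not None)
    assert sup1 == sup2
    assert all(0.0 <= s <= 100.0 for s in sup1)
    assert len(sup1) == 3   # 6-taxon unrooted tree has 3 internal edges
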