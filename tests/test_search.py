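"""NNI alternatives, incremental matrix updates, and hill climbing."""

import pytest

from dtlrec import (EventCosts, NniMove, fill_cost_matrix, hill_climb,
                    incremental_update, nni_alternatives, optimal_cost,
                    subdivide)
from dtlrec.search import InvalidMoveError
from dtlrec.trees import parse_dated_species_tree, parse_gene_tree
from helpers import random_instance
from dtlrec.evaluate import clade_set


class TestNniAlternatives:
    def test_three_leaf_swaps(self):
        G = parse_gene_tree("((a_A,b_B)50,c_C);")
        (v,) = G.internal_edges()
        g1, g2 = nni_alternatives(G, v)
        got = {frozenset(map(frozenset, clade_set(t))) for t in (g1, g2)}
        assert got == {
            frozenset({frozenset({"a_A", "c_C"})}),
            frozenset({frozenset({"b_B", "c_C"})}),
        }

    def test_involution(self):
        G = parse_gene_tree("(((a_A,b_B)50,c_C)60,d_D);")
        before = G.newick()
        for v in G.internal_edges():
            for choice in (0, 1):
                move = NniMove(v.id, choice)
                move.apply(G)
                assert G.newick() != before
                move.undo(G)
                assert G.newick() == before

    def test_caterpillar_yields_four_distinct_alternatives(self):
        G = parse_gene_tree("(((a_A,b_B)50,c_C)60,d_D);")
        seen = set()
        for v in G.internal_edges():
            for alt in nni_alternatives(G, v):
                seen.add(frozenset(clade_set(alt)))
        assert len(seen) == 4
        assert frozenset(clade_set(G)) not in seen

    def test_leaf_set_preserved(self):
        G = parse_gene_tree("(((a_A,b_B)50,c_C)60,d_D);")
        for v in G.internal_edges():
            for alt in nni_alternatives(G, v):
                assert alt.leaf_names() == G.leaf_names()

    def test_external_edge_rejected(self):
        G = parse_gene_tree("((a_A,b_B)50,c_C);")
        leaf = [n for n in G.postorder() if n.is_leaf][0]
        with pytest.raises(InvalidMoveError):
            nni_alternatives(G, leaf)
        with pytest.raises(InvalidMoveError):
            nni_alternatives(G, G.root)


class TestIncrementalUpdate:
    @pytest.mark.parametrize("seed", range(30))
    def test_completed_update_matches_full_refill(self, seed, hogenom):
        import random

        S, G = random_instance(n_species=3 + seed % 4, n_genes=8, seed=seed)
        Sp = subdivide(S)
        M = fill_cost_matrix(G, Sp, hogenom)
        rng = random.Random(seed)
        edges = G.internal_edges()
        if not edges:
            pytest.skip("no internal edge")
        v = rng.choice(edges)
        move = NniMove(v.id, rng.randrange(2))
        move.apply(G)
        h = G.height()
        new, verdict, n_cols = incremental_update(M, G, v.id)
        full = fill_cost_matrix(G, Sp, hogenom)
        assert n_cols <= h + 2
        if verdict == "completed":
            for u in G.postorder():
                assert new.c[u.id] == full.c[u.id]
                assert new.cbar[u.id] == full.cbar[u.id]
                assert new.tl[u.id] == full.tl[u.id]
                assert new.trace[u.id] == full.trace[u.id]
            assert new.optimal_cost() == full.optimal_cost()
        else:
            # rejection is sound: the rearranged tree is not better
            assert full.optimal_cost() >= M.optimal_cost()
        move.undo(G)

    def test_non_ancestor_columns_untouched(self, hogenom):
        S, G = random_instance(4, 8, seed=11)
        Sp = subdivide(S)
        M = fill_cost_matrix(G, Sp, hogenom)
        v = G.internal_edges()[0]
        ancestors = {v.id}
        a = v.parent
        while a is not None:
            ancestors.add(a.id)
            a = a.parent
        move = NniMove(v.id, 0)
        move.apply(G)
        new, verdict, _ = incremental_update(M, G, v.id)
        if verdict == "completed":
            for u in G.postorder():
                if u.id not in ancestors:
                    assert new.c[u.id] is M.c[u.id]  # shared, not recomputed
        move.undo(G)

    def test_symmetric_swap_is_rejected(self, hogenom):
        # all leaves in one species: any NNI leaves every column unchanged,
        # so the first dominance check fires
        S = parse_dated_species_tree("(A:1,B:1);")
        G = parse_gene_tree("((a1_A,a2_A)50,a3_A);")
        Sp = subdivide(S)
        M = fill_cost_matrix(G, Sp, hogenom)
        v = G.internal_edges()[0]
        move = NniMove(v.id, 0)
        move.apply(G)
        new, verdict, n_cols = incremental_update(M, G, v.id)
        assert verdict == "rejected"
        assert n_cols == 2  # v recomputed, then rejected at w
        move.undo(G)


class TestHillClimb:
    def test_threshold_zero_is_plain_reconciliation(self, hogenom):
        S, G = random_instance(4, 6, seed=3)
        Sp = subdivide(S)
        plain = optimal_cost(fill_cost_matrix(G, Sp, hogenom))
        tree, rec, trace = hill_climb(G, Sp, hogenom, threshold=0)
        assert trace.n_evaluations == 0
        assert trace.final_cost == plain
        assert tree.newick() == G.newick()

    def test_single_move_reaches_congruence(self, hogenom):
        S = parse_dated_species_tree("((A:1,B:1):1,C:2);")
        G = parse_gene_tree("((a_A,c_C)30,b_B);", species_names=set(S.leaves))
        Sp = subdivide(S)
        tree, rec, trace = hill_climb(G, Sp, hogenom, threshold=50)
        assert trace.final_cost == 0.0
        assert trace.n_accepted == 1
        assert frozenset({"a_A", "b_B"}) in clade_set(tree)

    def test_congruent_input_accepts_nothing(self, hogenom):
        S = parse_dated_species_tree("((A:1,B:1):1,C:2);")
        G = parse_gene_tree("((a_A,b_B)10,c_C);", species_names=set(S.leaves))
        Sp = subdivide(S)
        tree, rec, trace = hill_climb(G, Sp, hogenom, threshold=100)
        assert trace.n_accepted == 0
        assert trace.final_cost == 0.0

    @pytest.mark.parametrize("seed", range(12))
    def test_contracts_on_random_instances(self, seed, hogenom):
        S, G = random_instance(n_species=3 + seed % 4, n_genes=7, seed=200 + seed)
        Sp = subdivide(S)
        threshold = 65.0
        strong = {frozenset(v.leaf_names()) for v in G.internal_edges()
                  if v.support is not None and v.support >= threshold}
        tree, rec, trace = hill_climb(G, Sp, hogenom, threshold)
        assert tree.leaf_names() == G.leaf_names()
        # strong edges survive as clades of the output tree
        assert strong <= clade_set(tree) | {tree.leaf_names()}
        assert trace.final_cost <= trace.initial_cost
        costs_seq = [trace.initial_cost] + [c for *_, c in trace.accepted]
        assert all(a > b for a, b in zip(costs_seq, costs_seq[1:]))
        assert trace.final_cost == rec.recompute_cost(hogenom)

    @pytest.mark.parametrize("seed", range(10))
    def test_naive_and_optimized_agree(self, seed, hogenom):
        S, G = random_instance(n_species=3 + seed % 3, n_genes=8, seed=400 + seed)
        Sp = subdivide(S)
        t_opt = hill_climb(G, Sp, hogenom, 65.0, naive=False)
        t_nai = hill_climb(G, Sp, hogenom, 65.0, naive=True)
        assert t_opt[2].final_cost == t_nai[2].final_cost
        assert t_opt[0].newick() == t_nai[0].newick()
        assert [a[:2] for a in t_opt[2].accepted] == \
            [a[:2] for a in t_nai[2].accepted]
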