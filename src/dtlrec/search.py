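"""NNI hill climbing over weakly supported gene-tree edges.

An NNI around an internal edge ``(w, v)`` (``v`` the child) exchanges one of
the two subtrees hanging from ``v`` with the sibling subtree of ``v``.  The
hill climb visits weak edges in gene-tree postorder, evaluates both
alternatives of each, and adopts the cheaper one whenever it *strictly*
decreases the reconciliation cost; after an accepted move the scan restarts
from the first weak edge (an edge that failed earlier can become improving
after a later rearrangement, so no edge is retired).  Strict descent bounds
the number of accepted moves and guarantees termination.

An NNI only changes the descendant sets of ``v`` and its ancestors, so only
those columns of the DP matrix can change; they are recomputed bottom-up.
Moreover, if after recomputing the column of the changed-lineage child the
old column dominates the new one everywhere, no ancestor column — and hence
the optimal cost — can improve, and the candidate is rejected without
touching the rest of the matrix.  Each candidate thus costs at most
``h(G) + 2`` column recomputations instead of a full refill; a naive mode
that refills the whole matrix per candidate is kept for cross-checking and
benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reconcile import CostMatrix, backtrack, fill_cost_matrix

__all__ = [
    "NniMove",
    "SearchTrace",
    "InvalidMoveError",
    "nni_alternatives",
    "incremental_update",
    "hill_climb",
]


class InvalidMoveError(ValueError):
    """The requested edge does not support an NNI."""


@dataclass(frozen=True)
class NniMove:
    """NNI around the parent edge of node ``v`` (id ``v_id``); ``choice``
    selects which child of ``v`` (by position) is exchanged with the sibling
    subtree of ``v``.  Applying the same move twice restores the tree."""

    v_id: int
    choice: int  # 0 or 1: index into v.children at application time

    def apply(self, gene_tree):
        v = gene_tree.node_by_id[self.v_id]
        w = v.parent
        if w is None or v.is_leaf:
            raise InvalidMoveError("NNI requires an internal non-root edge")
        b_pos = 0 if w.children[1] is v else 1
        b = w.children[b_pos]
        c = v.children[self.choice]
        w.children[b_pos] = c
        c.parent = w
        v.children[self.choice] = b
        b.parent = v
        return gene_tree

    undo = apply  # involution


def nni_alternatives(gene_tree, v):
    """The two alternative trees reachable by NNI on the parent edge of ``v``.

    Returns ``(G_swap_first_child, G_swap_second_child)`` as independent
    copies; the input tree is untouched.
    """
    if isinstance(v, int):
        v = gene_tree.node_by_id[v]
    if v.parent is None or v.is_leaf:
        raise InvalidMoveError("NNI requires an internal non-root edge")
    out = []
    for choice in (0, 1):
        g = gene_tree.copy()
        NniMove(v.id, choice).apply(g)
        out.append(g)
    return tuple(out)


def incremental_update(matrix, gene_tree, v_id):
    """Recompute the DP matrix after an NNI already applied to ``gene_tree``.

    ``matrix`` must be the filled matrix of the tree *before* the move (its
    unchanged columns are still valid afterwards).  Columns of ``v``, its
    parent ``w`` and every strict ancestor of ``w`` are recomputed bottom-up.
    Starting from ``w``, whenever the previous column dominates the new one
    everywhere (``old <= new`` for all vertices) the candidate provably
    cannot beat the current tree and the ascent stops early.

    Returns ``(new_matrix_or_None, verdict, n_columns)`` where ``verdict`` is
    ``"completed"`` (exact matrix for the new tree) or ``"rejected"``.
    """
    v = gene_tree.node_by_id[v_id]
    w = v.parent
    if w is None or v.is_leaf:
        raise InvalidMoveError("NNI requires an internal non-root edge")
    new = matrix.share()
    new.gene_tree = gene_tree
    path = [v, w]
    anc = w.parent
    while anc is not None:
        path.append(anc)
        anc = anc.parent
    n_cols = 0
    for node in path:
        cols = new.fill_column(node)
        new.store_column(node.id, cols)
        n_cols += 1
        if node is not v:  # dominance test applies from w upward
            old_c = matrix.c[node.id]
            new_c = cols[0]
            if all(o <= n for o, n in zip(old_c, new_c)):
                return None, "rejected", n_cols
    return new, "completed", n_cols


@dataclass
class SearchTrace:
    """Bookkeeping of a hill climb."""

    initial_cost: float = 0.0
    final_cost: float = 0.0
    accepted: list = field(default_factory=list)  # (v_id, choice, before, after)
    n_evaluations: int = 0
    n_columns_recomputed: int = 0
    n_cells_recomputed: int = 0

    @property
    def n_accepted(self):
        return len(self.accepted)


def hill_climb(gene_tree, subdivision, costs, threshold,
               naive=False, missing_weak=False):
    """Minimise the reconciliation cost over NNIs of weak edges.

    Operates on a copy of ``gene_tree``; strong edges (support >=
    ``threshold``) are never rearranged, so they survive into the output.
    Returns ``(tree, reconciliation, trace)`` where the reconciliation is a
    most parsimonious one for the final tree.
    """
    G = gene_tree.copy()
    n_vertices = len(subdivision.vertices)
    matrix = fill_cost_matrix(G, subdivision, costs)
    cost = matrix.optimal_cost()
    trace = SearchTrace(initial_cost=cost)

    improved = True
    while improved:
        improved = False
        weak = G.weak_edges(threshold, missing_weak=missing_weak)
        for v in weak:
            best = None  # (cost, choice, matrix)
            for choice in (0, 1):
                move = NniMove(v.id, choice)
                move.apply(G)
                trace.n_evaluations += 1
                if naive:
                    cand = CostMatrix(G, subdivision, costs).fill()
                    cand_cost = cand.optimal_cost()
                    trace.n_columns_recomputed += len(G)
                else:
                    cand, verdict, n_cols = incremental_update(matrix, G, v.id)
                    trace.n_columns_recomputed += n_cols
                    cand_cost = cand.optimal_cost() if cand is not None else None
                move.undo(G)
                if cand_cost is not None and cand_cost < cost:
                    if best is None or cand_cost < best[0]:
                        best = (cand_cost, choice, cand)
            if best is not None:
                cand_cost, choice, cand = best
                NniMove(v.id, choice).apply(G)
                matrix = cand if cand is not None else fill_cost_matrix(
                    G, subdivision, costs)
                matrix.gene_tree = G
                trace.accepted.append((v.id, choice, cost, cand_cost))
                cost = cand_cost
                improved = True
                break  # rescan weak edges from the start

    trace.final_cost = cost
    trace.n_cells_recomputed = trace.n_columns_recomputed * n_vertices
    reconciliation = backtrack(matrix)
    return G, reconciliation, trace
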