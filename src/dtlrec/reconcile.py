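"""Most parsimonious DTL reconciliation by dynamic programming.

A reconciliation maps every gene-tree node ``u`` onto an ordered sequence of
vertices of the subdivided species tree, each step labelled with one atomic
event:

========  =====================================================
``C``     contemporaneous leaf match (gene leaf in its species)
``S``     speciation — the two gene children descend into the
          two species children
``D``     duplication within the current species branch
``T``     horizontal transfer — one child stays, the other jumps
          to a contemporaneous vertex of the same time slice
``E``     no event — descent through an artificial vertex
``SL``    speciation where the copy in one species child is lost
``TL``    transfer where the non-transferred copy is lost
========  =====================================================

The cost of a reconciliation is ``d*dup + t*trans + l*loss`` where a ``TL``
contributes one transfer and one loss and an ``SL`` one loss.  Speciations
are free by default, but a nonzero speciation cost is supported (it then
also enters the composite ``SL``).

The optimal cost is computed by a dynamic program over the matrix
``(gene node u, subdivision vertex x)``.  For each cell, the cheapest
non-``TL`` scenario ``cbar(u, x)`` is computed first; the ``TL`` scenario
then reads the best (or second best, when the best sits at ``x`` itself)
``cbar`` value within the time slice of ``x``, so that the whole fill takes
O(|S'| * |G|) cell updates.  Within a column the slice-internal order is:
``cbar`` for every slice vertex, then the slice best-receiver summary, then
the ``TL`` completion — an optimal sequence never contains two consecutive
``TL`` steps, so ``TL`` may always be resolved against non-``TL`` costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

INF = math.inf

__all__ = [
    "EventCosts",
    "CostMatrix",
    "Reconciliation",
    "NoReconciliationError",
    "fill_cost_matrix",
    "optimal_cost",
    "backtrack",
    "reconciliation_cost",
]


@dataclass(frozen=True)
class EventCosts:
    """Per-event costs; the composite TL costs ``trans + loss``, SL
    ``spec + loss``.  The ``hogenom`` profile (dup=3.5, trans=3, loss=1) is
    the shipped default."""

    dup: float = 3.5
    trans: float = 3.0
    loss: float = 1.0
    spec: float = 0.0

    def __post_init__(self):
        if min(self.dup, self.trans, self.loss, self.spec) < 0:
            raise ValueError("event costs must be nonnegative")

    @classmethod
    def hogenom(cls):
        return cls(dup=3.5, trans=3.0, loss=1.0, spec=0.0)


class NoReconciliationError(RuntimeError):
    """Raised when backtracking is requested on an infeasible instance."""


class CostMatrix:
    """DP matrix over (gene node, subdivision vertex).

    Per gene node ``u`` the matrix holds four parallel per-vertex arrays:

    * ``c[u]``     — optimal cost of mapping ``u`` at the vertex;
    * ``cbar[u]``  — optimal cost excluding a leading ``TL`` step;
    * ``trace[u]`` — the event achieving ``cbar`` (tie-broken by the fixed
      priority C > S > D > T > E > SL, then lower gene-child index, then
      lower vertex id, i.e. slice order);
    * ``tl[u]``    — receiver vertex id when ``c`` is achieved by a leading
      ``TL`` (strictly cheaper than ``cbar``), else ``-1``.

    Columns are filled one gene node at a time in postorder; within a column
    slices are visited in increasing time, which satisfies every dependency
    of the recurrences.  The same column routine serves both the initial
    fill and the incremental NNI update, so recomputed columns are bitwise
    reproducible.
    """

    def __init__(self, gene_tree, subdivision, costs):
        self.gene_tree = gene_tree
        self.subdivision = subdivision
        self.costs = costs
        self.c = {}
        self.cbar = {}
        self.trace = {}
        self.tl = {}
        self.n_cell_updates = 0

    # -- column fill ------------------------------------------------------

    def fill_column(self, u):
        """(Re)compute the column of gene node ``u`` from its children's
        columns; returns the new ``(c, cbar, trace, tl)`` arrays without
        storing them."""
        Sp = self.subdivision
        cost = self.costs
        m = len(Sp.vertices)
        c = [INF] * m
        cbar = [INF] * m
        trace = [None] * m
        tl = [-1] * m

        leaf = u.is_leaf
        if leaf:
            target = Sp.leaf_vertex.get(self.gene_tree.species_of[u.name])
            c1 = c2 = None
        else:
            c1 = self.c[u.children[0].id]
            c2 = self.c[u.children[1].id]

        for sl in Sp.slices:
            # cbar for every vertex of the slice
            for vid in sl:
                x = Sp.vertices[vid]
                best = INF
                ev = None
                if leaf:
                    if vid == target:
                        best, ev = 0.0, ("C",)
                else:
                    if len(x.children) == 2:
                        xa, xb = x.children[0].id, x.children[1].id
                        v1 = c1[xa] + c2[xb]
                        v2 = c1[xb] + c2[xa]
                        if v1 <= v2:
                            cand, asg = v1 + cost.spec, ("S", xa, xb)
                        else:
                            cand, asg = v2 + cost.spec, ("S", xb, xa)
                        if cand < best:
                            best, ev = cand, asg
                    cand = c1[vid] + c2[vid] + cost.dup
                    if cand < best:
                        best, ev = cand, ("D",)
                    # T handled after slice minima are known (below)
                if len(x.children) == 1:
                    cand = c[x.children[0].id]
                    if cand < best:
                        best, ev = cand, ("E", x.children[0].id)
                elif len(x.children) == 2:
                    xa, xb = x.children[0].id, x.children[1].id
                    if c[xa] <= c[xb]:
                        cand, step = c[xa] + cost.loss + cost.spec, ("SL", xa, xb)
                    else:
                        cand, step = c[xb] + cost.loss + cost.spec, ("SL", xb, xa)
                    if cand < best:
                        best, ev = cand, step
                cbar[vid] = best
                trace[vid] = ev
                self.n_cell_updates += 1

            # transfer events need the slice-wise best/second-best of the
            # children's full costs; they are folded into cbar here, before
            # the TL completion, because a T is itself a non-TL scenario.
            if not leaf and len(sl) >= 2:
                b1a = b2a = b1b = b2b = INF
                i1a = i1b = -1
                for vid in sl:
                    v = c1[vid]
                    if v < b1a:
                        b2a, b1a, i1a = b1a, v, vid
                    elif v < b2a:
                        b2a = v
                    v = c2[vid]
                    if v < b1b:
                        b2b, b1b, i1b = b1b, v, vid
                    elif v < b2b:
                        b2b = v
                for vid in sl:
                    # a T that ties the E/SL scenario wins: the fixed event
                    # priority is C > S > D > T > E > SL
                    def t_beats(cand):
                        if cand < cbar[vid]:
                            return True
                        tr = trace[vid]
                        return (cand == cbar[vid] and cand < INF
                                and tr is not None and tr[0] in ("E", "SL"))

                    # u1 stays at x, u2 is transferred (preferred on ties)
                    recv2 = i1b if i1b != vid else -1
                    best2 = b1b if i1b != vid else b2b
                    if recv2 < 0 and best2 < INF:
                        recv2 = self._arg_excl(c2, sl, vid, best2)
                    cand = c1[vid] + best2 + cost.trans
                    if t_beats(cand):
                        cbar[vid] = cand
                        trace[vid] = ("T", 1, recv2)
                    recv1 = i1a if i1a != vid else -1
                    best1 = b1a if i1a != vid else b2a
                    if recv1 < 0 and best1 < INF:
                        recv1 = self._arg_excl(c1, sl, vid, best1)
                    cand = c2[vid] + best1 + cost.trans
                    if cand < cbar[vid]:
                        cbar[vid] = cand
                        trace[vid] = ("T", 2, recv1)

            # slice best/second-best of cbar for the TL completion
            if len(sl) >= 2:
                t1 = t2 = INF
                a1 = -1
                for vid in sl:
                    v = cbar[vid]
                    if v < t1:
                        t2, t1, a1 = t1, v, vid
                    elif v < t2:
                        t2 = v
                for vid in sl:
                    if a1 != vid:
                        recv, val = a1, t1
                    else:
                        val = t2
                        recv = self._arg_excl(cbar, sl, vid, t2) if t2 < INF else -1
                    ctl = val + cost.trans + cost.loss
                    if ctl < cbar[vid]:
                        c[vid] = ctl
                        tl[vid] = recv
                    else:
                        c[vid] = cbar[vid]
            else:
                for vid in sl:
                    c[vid] = cbar[vid]
        return c, cbar, trace, tl

    @staticmethod
    def _arg_excl(arr, sl, excl, value):
        """First slice vertex other than ``excl`` achieving ``value``."""
        for vid in sl:
            if vid != excl and arr[vid] == value:
                return vid
        return -1

    def store_column(self, uid, cols):
        self.c[uid], self.cbar[uid], self.trace[uid], self.tl[uid] = cols

    def fill(self):
        for u in self.gene_tree.postorder():
            self.store_column(u.id, self.fill_column(u))
        return self

    # -- results ----------------------------------------------------------

    def optimal_cost(self):
        root = self.gene_tree.root.id
        return min(self.c[root])

    def optimal_root_vertex(self):
        root = self.c[self.gene_tree.root.id]
        best = min(root)
        if best == INF:
            return -1
        return root.index(best)

    def share(self):
        """Shallow copy sharing column arrays; used by the NNI update."""
        other = CostMatrix(self.gene_tree, self.subdivision, self.costs)
        other.c = dict(self.c)
        other.cbar = dict(self.cbar)
        other.trace = dict(self.trace)
        other.tl = dict(self.tl)
        return other


@dataclass
class Reconciliation:
    """One most parsimonious reconciliation.

    ``alpha`` maps each gene node id to its ordered sequence of
    ``(vertex id, event)`` steps; the last step carries the terminal event
    (C, S, D or T), earlier steps are E, SL or TL descents.
    """

    alpha: dict = field(default_factory=dict)
    duplications: int = 0
    transfers: int = 0
    losses: int = 0
    speciations: int = 0  # S and SL events jointly
    cost: float = 0.0

    def events(self):
        for uid, seq in self.alpha.items():
            for vid, ev in seq:
                yield uid, vid, ev

    def recompute_cost(self, costs):
        """Re-evaluate the cost formula from the stored event counts."""
        return reconciliation_cost(self.duplications, self.transfers,
                                   self.losses, costs,
                                   speciations=self.speciations)


def fill_cost_matrix(gene_tree, subdivision, costs):
    """Fill the DP cost matrix for a gene tree against a subdivision."""
    for leaf in gene_tree.leaves():
        sp = gene_tree.species_of[leaf.name]
        if sp not in subdivision.leaf_vertex:
            from .trees import GeneMappingError

            raise GeneMappingError(
                f"gene leaf {leaf.name} maps to species {sp!r} absent from "
                "the species tree"
            )
    return CostMatrix(gene_tree, subdivision, costs).fill()


def optimal_cost(matrix):
    """Optimal reconciliation cost; ``inf`` when no reconciliation exists."""
    return matrix.optimal_cost()


def backtrack(matrix):
    """Extract one most parsimonious reconciliation from a filled matrix.

    Deterministic: ties were resolved during the fill by the fixed event
    priority, then lower gene-child index, then vertex order within the
    slice; the root is placed at the lowest-id optimal vertex.
    """
    G = matrix.gene_tree
    best_vid = matrix.optimal_root_vertex()
    if best_vid < 0:
        raise NoReconciliationError("instance admits no finite-cost reconciliation")
    rec = Reconciliation()
    stack = [(G.root, best_vid)]
    while stack:
        u, vid = stack.pop()
        uid = u.id
        seq = []
        while True:
            recv = matrix.tl[uid][vid]
            if recv >= 0:
                seq.append((vid, "TL"))
                rec.transfers += 1
                rec.losses += 1
                vid = recv
                # after a TL the continuation is the non-TL scenario at the
                # receiver (no two consecutive TL steps)
            ev = matrix.trace[uid][vid]
            kind = ev[0]
            if kind == "C":
                seq.append((vid, "C"))
                break
            if kind == "S":
                seq.append((vid, "S"))
                rec.speciations += 1
                stack.append((u.children[0], ev[1]))
                stack.append((u.children[1], ev[2]))
                break
            if kind == "D":
                seq.append((vid, "D"))
                rec.duplications += 1
                stack.append((u.children[0], vid))
                stack.append((u.children[1], vid))
                break
            if kind == "T":
                seq.append((vid, "T"))
                rec.transfers += 1
                if ev[1] == 1:
                    stack.append((u.children[0], vid))
                    stack.append((u.children[1], ev[2]))
                else:
                    stack.append((u.children[0], ev[2]))
                    stack.append((u.children[1], vid))
                break
            if kind == "E":
                seq.append((vid, "E"))
                vid = ev[1]
                continue
            if kind == "SL":
                seq.append((vid, "SL"))
                rec.losses += 1
                rec.speciations += 1
                vid = ev[1]
                continue
            raise AssertionError(f"corrupt traceback entry {ev!r}")
        rec.alpha[uid] = seq
    rec.cost = reconciliation_cost(rec.duplications, rec.transfers, rec.losses,
                                   matrix.costs, speciations=rec.speciations)
    return rec


def reconciliation_cost(duplications, transfers, losses, costs, speciations=0):
    """Cost formula ``d*dup + t*trans + l*loss (+ s*spec)``; a TL counts one
    transfer and one loss, an SL one loss (and one speciation)."""
    if min(duplications, transfers, losses, speciations) < 0:
        raise ValueError("event counts must be nonnegative")
    return (duplications * costs.dup + transfers * costs.trans
            + losses * costs.loss + speciations * costs.spec)
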