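"""Independent oracles and instance builders shared by the test suite.

Everything here deliberately avoids the production code paths: the
reconciliation oracle is a memoised recursive enumeration of atomic event
sequences (termination follows from forbidding the second of two consecutive
transfer-plus-loss steps, which can never be part of a cheapest sequence),
and the RF oracle extracts clades with its own traversal.
"""

from __future__ import annotations

import math
import random

from dtlrec.trees import DatedSpeciesTree, GeneTree, Node

INF = math.inf


# -- building trees from nested tuples ------------------------------------


def node_from_nested(nested):
    if isinstance(nested, str):
        return Node(name=nested)
    n = Node()
    for part in nested:
        ch = node_from_nested(part)
        ch.parent = n
        n.children.append(ch)
    return n


def species_tree_from_nested(nested, ages=None):
    """Build a dated species tree; without explicit ages each internal node
    sits one unit above its highest child (leaves at 0)."""
    root = node_from_nested(nested)
    for i, n in enumerate(root.postorder()):
        n.id = i
    tree = DatedSpeciesTree(root)
    if ages is None:
        for n in tree.nodes:  # postorder: children first
            n.time = 0.0 if n.is_leaf else max(c.time for c in n.children) + 1.0
    else:
        for n in tree.nodes:
            n.time = ages[n.name]
    tree.validate_times()
    return tree


def gene_tree_from_nested(nested, species_of, supports=None):
    root = node_from_nested(nested)
    for i, n in enumerate(root.postorder()):
        n.id = i
        if n.children and n.parent is not None and supports is not None:
            n.support = supports.get(i)
    return GeneTree(root, species_of)


def all_topologies(labels):
    """All rooted binary leaf-labelled topologies as nested tuples:
    1, 1, 3, 15, 105 trees for 1-5 leaves."""
    labels = list(labels)
    if len(labels) == 1:
        return [labels[0]]
    first, rest = labels[0], labels[1:]
    out = []
    for mask in range(2 ** len(rest)):
        left = [first] + [x for i, x in enumerate(rest) if mask >> i & 1]
        right = [x for i, x in enumerate(rest) if not mask >> i & 1]
        if not right:
            continue
        for tl in all_topologies(left):
            for tr in all_topologies(right):
                out.append((tl, tr))
    return out


def random_topology(labels, rng):
    labels = list(labels)
    if len(labels) == 1:
        return labels[0]
    k = rng.randint(1, len(labels) - 1)
    idx = rng.sample(range(len(labels)), k)
    left = [labels[i] for i in idx]
    right = [x for i, x in enumerate(labels) if i not in idx]
    return (random_topology(left, rng), random_topology(right, rng))


def random_instance(n_species, n_genes, seed, supports=True):
    """Random dated species tree + random mapped gene tree."""
    rng = random.Random(seed)
    sp_labels = [chr(ord("A") + i) for i in range(n_species)]
    species = species_tree_from_nested(random_topology(sp_labels, rng))
    # perturb internal ages to random distinct values, preserving order
    internals = [n for n in species.nodes if not n.is_leaf]
    for n in sorted(internals, key=lambda n: n.time):
        base = max(c.time for c in n.children)
        n.time = base + rng.uniform(0.2, 1.5)
    species.validate_times()
    gene_labels = [f"g{i}_{rng.choice(sp_labels)}" for i in range(n_genes)]
    species_of = {g: g.rsplit("_", 1)[-1] for g in gene_labels}
    supp = None
    g = gene_tree_from_nested(random_topology(gene_labels, rng), species_of)
    if supports:
        for v in g.internal_edges():
            v.support = rng.choice([10.0, 30.0, 60.0, 90.0, 100.0])
    return species, g


# -- reconciliation oracle -------------------------------------------------


def oracle_cost(gene_tree, subdivision, costs):
    """Minimum reconciliation cost by enumeration of atomic event sequences.

    Recursive over (gene node, vertex, just-after-TL); within each call all
    atomic events of the model are tried literally, including every transfer
    receiver of the time slice (no best-receiver shortcut).
    """
    verts = subdivision.vertices
    slices = subdivision.slices
    species_of = gene_tree.species_of
    memo = {}

    def best(u, x, after_tl):
        key = (u.id, x, after_tl)
        if key in memo:
            return memo[key]
        v = verts[x]
        nch = len(v.children)
        cands = []
        if u.is_leaf:
            if nch == 0 and v.s_node.name == species_of[u.name]:
                cands.append(0.0)
        else:
            u1, u2 = u.children
            if nch == 2:
                a, b = v.children[0].id, v.children[1].id
                cands.append(costs.spec + best(u1, a, False) + best(u2, b, False))
                cands.append(costs.spec + best(u1, b, False) + best(u2, a, False))
            cands.append(costs.dup + best(u1, x, False) + best(u2, x, False))
            for y in slices[v.slice]:
                if y != x:
                    cands.append(costs.trans + best(u1, x, False)
                                 + best(u2, y, False))
                    cands.append(costs.trans + best(u1, y, False)
                                 + best(u2, x, False))
        if nch == 1:
            cands.append(best(u, v.children[0].id, False))
        elif nch == 2:
            for ch in v.children:
                cands.append(costs.spec + costs.loss + best(u, ch.id, False))
        if not after_tl:
            for y in slices[v.slice]:
                if y != x:
                    cands.append(costs.trans + costs.loss + best(u, y, True))
        result = min(cands, default=INF)
        memo[key] = result
        return result

    root = gene_tree.root
    return min(best(root, x, False) for x in range(len(verts)))


# -- RF oracle -------------------------------------------------------------


def oracle_clades(root):
    """Clade extraction with an explicitly recursive traversal."""
    clades = []

    def rec(n):
        if not n.children:
            return frozenset([n.name])
        below = frozenset()
        for ch in n.children:
            below = below | rec(ch)
        clades.append(below)
        return below

    whole = rec(root)
    return {c for c in clades if c != whole}


def oracle_rf(t1, t2):
    r1 = t1.root if hasattr(t1, "root") else t1
    r2 = t2.root if hasattr(t2, "root") else t2
    return len(oracle_clades(r1) ^ oracle_clades(r2))


# -- independent pruning filter -------------------------------------------


def oracle_prune(root, extinct):
    """Reference pruning: keep the subtree spanned by the living leaves."""
    def rec(n):
        if not n.children:
            return None if n.name in extinct else Node(name=n.name)
        kept = [rec(c) for c in n.children]
        kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        m = Node()
        m.children = kept
        for k in kept:
            k.parent = m
        return m

    return rec(root)
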