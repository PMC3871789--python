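"""Dated species trees, support-annotated gene trees, and the time-sliced subdivision.

The reconciliation engine works on three tree-shaped structures:

* :class:`DatedSpeciesTree` — a rooted binary species tree whose nodes carry
  ages (time before present).  Ages are either derived from ultrametric
  branch lengths or supplied explicitly via a node-date table.
* :class:`SubdividedSpeciesTree` — the species tree augmented with
  single-child *artificial* vertices so that every vertex is contemporaneous
  with every other vertex of its *time slice*.  Horizontal transfers are only
  permitted between vertices of the same slice, which makes time consistency
  a purely combinatorial property.
* :class:`GeneTree` — a rooted binary gene tree whose internal edges carry
  support values and whose leaves are mapped to species.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "TreeError",
    "StructuralError",
    "DatingError",
    "LabelError",
    "GeneMappingError",
    "Node",
    "DatedSpeciesTree",
    "SVertex",
    "SubdividedSpeciesTree",
    "GeneTree",
    "parse_dated_species_tree",
    "parse_gene_tree",
    "subdivide",
    "weak_edges",
]


class TreeError(ValueError):
    """Base class for tree validation errors."""


class StructuralError(TreeError):
    """Tree is not rooted binary."""


class DatingError(TreeError):
    """Branch lengths are not ultrametric and no date table was given."""


class LabelError(TreeError):
    """Duplicate or missing leaf labels."""


class GeneMappingError(TreeError):
    """A gene leaf maps to a species absent from the species tree."""


class Node:
    """A tree node; used for both species and gene trees.

    ``time`` is the age of a species node; ``support`` the edge support of the
    parent edge of an internal gene node (``None`` when absent).
    """

    __slots__ = ("id", "name", "length", "support", "time", "children", "parent")

    def __init__(self, id=-1, name=None, length=None):
        self.id = id
        self.name = name
        self.length = length
        self.support = None
        self.time = 0.0
        self.children = []
        self.parent = None

    @property
    def is_leaf(self):
        return not self.children

    def postorder(self):
        stack, out = [(self, False)], []
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))
        return out

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self):
        return frozenset(n.name for n in self.leaves())

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.id} {self.name or ''}>"


def _parse_newick(text, support_dialect="label"):
    """Parse a newick string into a :class:`Node` tree.

    ``support_dialect`` selects where internal-edge supports live: ``label``
    reads them from internal node labels (RAxML style), ``comment`` from
    bracketed comments attached to internal nodes.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # normalise dendropy's parse errors
        if "Duplicate taxon" in str(exc):
            raise LabelError(f"duplicate leaf labels: {exc}") from exc
        raise TreeError(f"newick parse error: {exc}") from exc

    def convert(dnode):
        node = Node(length=dnode.edge.length)
        if dnode.taxon is not None:
            node.name = dnode.taxon.label
        elif dnode.label is not None:
            node.name = dnode.label
        for dch in dnode.child_nodes():
            ch = convert(dch)
            ch.parent = node
            node.children.append(ch)
        if node.children:
            raw = None
            if support_dialect == "comment":
                if dnode.comments:
                    raw = dnode.comments[0]
            else:
                raw = dnode.label
            if raw is not None:
                try:
                    node.support = float(raw)
                except ValueError:
                    node.support = None
        return node

    root = convert(dtree.seed_node)
    for i, n in enumerate(root.postorder()):
        n.id = i
    return root


def _check_binary(root):
    for n in root.postorder():
        if n.children and len(n.children) != 2:
            raise StructuralError(
                f"node {n.name or n.id} has {len(n.children)} children; "
                "trees must be rooted binary"
            )


def _write_newick(root, with_support=False, with_length=True, decorate=None):
    buf = _io.StringIO()

    def rec(n):
        if n.children:
            buf.write("(")
            for i, ch in enumerate(n.children):
                if i:
                    buf.write(",")
                rec(ch)
            buf.write(")")
            if with_support and n.parent is not None and n.support is not None:
                sup = n.support
                buf.write(f"{sup:g}")
            elif n.name:
                buf.write(n.name)
        else:
            buf.write(n.name or "")
        if decorate is not None:
            buf.write(decorate(n))
        if with_length and n.length is not None:
            buf.write(f":{n.length:g}")

    rec(root)
    buf.write(";")
    return buf.getvalue()


class DatedSpeciesTree:
    """Rooted binary species tree with a strict node time (age) function.

    Ages strictly decrease from parent to child; extant leaves sit at age 0.
    Internal nodes without explicit names are assigned stable keys ``S<i>``
    (preorder numbering) used in date tables and event locations.
    """

    def __init__(self, root):
        self.root = root
        _check_binary(root)
        self._assign_keys()
        self.nodes = root.postorder()
        leaves = [n for n in self.nodes if n.is_leaf]
        names = [n.name for n in leaves]
        if len(set(names)) != len(names):
            raise LabelError("duplicate species leaf labels")
        if any(n.name is None for n in leaves):
            raise LabelError("unnamed species leaf")
        self.leaves = {n.name: n for n in leaves}
        self.node_by_key = {n.name: n for n in self.nodes}

    def _assign_keys(self):
        # preorder traversal; unnamed internal nodes get stable S<i> keys
        taken = {n.name for n in self.root.postorder() if n.name}
        counter = 0
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.children and not n.name:
                while f"S{counter}" in taken:
                    counter += 1
                n.name = f"S{counter}"
                taken.add(n.name)
            counter += 1
            for ch in reversed(n.children):
                stack.append(ch)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text, dates=None, tol=1e-6):
        root = _parse_newick(text)
        tree = cls(root)
        if dates is None:
            tree._dates_from_lengths(tol)
        else:
            tree._dates_from_table(dates)
        tree.validate_times()
        return tree

    def _dates_from_lengths(self, tol):
        depth = {self.root.id: 0.0}
        order = [n for n in self.root.postorder()][::-1]  # preorder-ish
        for n in order:
            if n.parent is not None:
                if n.length is None:
                    raise DatingError(
                        f"branch length missing above {n.name or n.id}"
                    )
                depth[n.id] = depth[n.parent.id] + n.length
        height = max(depth[l.id] for l in self.leaves.values())
        for l in self.leaves.values():
            if abs(depth[l.id] - height) > tol:
                raise DatingError(
                    "branch lengths are not ultrametric "
                    f"(leaf {l.name} depth {depth[l.id]:g} != height {height:g}); "
                    "supply a node-date table"
                )
        for n in self.nodes:
            age = height - depth[n.id]
            n.time = 0.0 if n.is_leaf else age

    def _dates_from_table(self, dates):
        for n in self.nodes:
            if n.name in dates:
                n.time = float(dates[n.name])
            elif n.is_leaf:
                n.time = 0.0
            else:
                raise DatingError(f"no date for internal node {n.name}")

    def validate_times(self):
        for n in self.nodes:
            if n.time < 0:
                raise DatingError(f"negative age at {n.name}")
            for ch in n.children:
                if not ch.time < n.time:
                    raise DatingError(
                        f"age of {ch.name} ({ch.time:g}) not below its parent "
                        f"{n.name} ({n.time:g})"
                    )

    # -- views ------------------------------------------------------------

    @property
    def height(self):
        return self.root.time

    def newick(self):
        return _write_newick(self.root, with_length=True)

    def __len__(self):
        return len(self.nodes)


class SVertex:
    """Vertex of the subdivided species tree.

    Artificial vertices have exactly one child and remember the original
    species-tree edge they subdivide through ``host``, the edge's lower
    endpoint.  ``branch`` identifies the original species branch containing
    the vertex (its own node for real vertices, the host edge's lower node
    for artificial ones); event locations are reported at this resolution.
    """

    __slots__ = ("id", "time", "children", "parent", "s_node", "host", "slice")

    def __init__(self, time, s_node=None, host=None):
        self.id = -1
        self.time = time
        self.children = []
        self.parent = None
        self.s_node = s_node  # original Node, None when artificial
        self.host = host  # original lower-endpoint Node for artificial vertices
        self.slice = -1

    @property
    def is_artificial(self):
        return self.s_node is None

    @property
    def branch(self):
        return self.host.name if self.is_artificial else self.s_node.name

    @property
    def name(self):
        if self.is_artificial:
            return f"{self.host.name}@{self.time:g}"
        return self.s_node.name

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<SVertex {self.id} {self.name}>"


class SubdividedSpeciesTree:
    """Subdivision of a dated species tree into contemporaneous time slices.

    For every internal node age ``t`` and every species edge strictly
    spanning ``t``, one artificial single-child vertex is inserted on that
    edge at time ``t``.  Vertices sharing an age (within ``tol``) form a
    *slice*; slices are ordered by increasing time and transfers are only
    allowed within a slice.
    """

    def __init__(self, species_tree, tol=1e-9):
        self.species_tree = species_tree
        self.tol = tol
        self._build()

    def _build(self):
        S = self.species_tree
        internal_times = []
        for n in S.nodes:
            if not n.is_leaf:
                t = n.time
                if not any(abs(t - u) <= self.tol for u in internal_times):
                    internal_times.append(t)
        internal_times.sort()

        verts = []
        s_vertex = {}
        for n in S.nodes:
            v = SVertex(n.time, s_node=n)
            s_vertex[n.id] = v
            verts.append(v)
        # chain artificial vertices along each spanning edge, top-down
        for n in S.nodes:
            if n.parent is None:
                continue
            lo, hi = n.time, n.parent.time
            inner = [t for t in internal_times if lo < t < hi
                     and abs(t - lo) > self.tol and abs(t - hi) > self.tol]
            upper = s_vertex[n.parent.id]
            for t in sorted(inner, reverse=True):
                w = SVertex(t, host=n)
                verts.append(w)
                upper.children.append(w)
                w.parent = upper
                upper = w
            upper.children.append(s_vertex[n.id])
            s_vertex[n.id].parent = upper

        # group into slices by time (ascending), assign ids in slice order
        times = []
        for v in verts:
            if not any(abs(v.time - t) <= self.tol for t in times):
                times.append(v.time)
        times.sort()
        slice_index = {i: min(range(len(times)),
                              key=lambda k: abs(times[k] - v.time))
                       for i, v in enumerate(verts)}
        order = sorted(range(len(verts)), key=lambda i: (slice_index[i], i))
        self.vertices = []
        for rank, i in enumerate(order):
            v = verts[i]
            v.id = rank
            v.slice = slice_index[i]
            self.vertices.append(v)
        self.slices = [[] for _ in times]
        for v in self.vertices:
            self.slices[v.slice].append(v.id)
        self.slice_times = times
        self.root = s_vertex[S.root.id]
        self.leaf_vertex = {name: s_vertex[n.id].id for name, n in S.leaves.items()}
        self.n_artificial = sum(1 for v in self.vertices if v.is_artificial)

    def __len__(self):
        return len(self.vertices)

    def branch_of(self, vid):
        """Original species branch (lower-endpoint node name) containing ``vid``."""
        return self.vertices[vid].branch

    def validate(self):
        """Check the structural invariants of the subdivision."""
        for v in self.vertices:
            n_ch = len(v.children)
            if v.is_artificial:
                assert n_ch == 1, "artificial vertex must have one child"
            else:
                assert n_ch in (0, 2), "species vertex must keep 0 or 2 children"
            for ch in v.children:
                assert ch.time < v.time + self.tol
                assert ch.parent is v
        for sl in self.slices:
            ts = [self.vertices[i].time for i in sl]
            assert max(ts) - min(ts) <= 2 * self.tol


class GeneTree:
    """Rooted binary gene tree with per-internal-edge supports.

    Each leaf carries a unique gene identifier and is assigned to a species
    through ``species_of``.  Supports live on the parent edges of internal
    non-root nodes (``node.support``); a missing support means the edge is
    treated as strong unless ``missing_weak`` is requested when listing weak
    edges.  Node ids are stable under NNI rearrangement, which only rewires
    ``children``/``parent`` links.
    """

    def __init__(self, root, species_of):
        self.root = root
        _check_binary(root)
        nodes = root.postorder()
        names = [n.name for n in nodes if n.is_leaf]
        if len(set(names)) != len(names):
            raise LabelError("duplicate gene leaf labels")
        self.species_of = dict(species_of)
        for n in nodes:
            if n.is_leaf and n.name not in self.species_of:
                raise GeneMappingError(f"no species mapping for gene leaf {n.name}")
        self.node_by_id = {n.id: n for n in nodes}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text, mapping=None, separator="_",
                    species_names=None, support_dialect="label"):
        """Parse a gene tree; resolve species by suffix rule or explicit map.

        With the suffix rule the species is the last ``separator``-delimited
        token of the leaf label.  ``mapping`` (gene leaf -> species) overrides.
        When ``species_names`` is given, every resolved species must be in it.
        """
        root = _parse_newick(text, support_dialect=support_dialect)
        species_of = {}
        for leaf in root.leaves():
            if mapping is not None and leaf.name in mapping:
                sp = mapping[leaf.name]
            else:
                sp = leaf.name.rsplit(separator, 1)[-1]
            species_of[leaf.name] = sp
        if species_names is not None:
            for g, sp in species_of.items():
                if sp not in species_names:
                    raise GeneMappingError(
                        f"gene leaf {g} maps to species {sp!r} absent from the "
                        "species tree"
                    )
        return cls(root, species_of)

    # -- views ------------------------------------------------------------

    def postorder(self):
        return self.root.postorder()

    def leaves(self):
        return self.root.leaves()

    def leaf_names(self):
        return self.root.leaf_names()

    def internal_edges(self):
        """Internal edges, each named by its lower endpoint ``v`` of ``(w, v)``."""
        return [n for n in self.postorder()
                if n.children and n.parent is not None]

    def weak_edges(self, threshold, missing_weak=False):
        """Internal edges with support strictly below ``threshold``."""
        if not 0 <= threshold <= 100:
            raise ValueError("threshold must lie in [0, 100]")
        out = []
        for v in self.internal_edges():
            if v.support is None:
                if missing_weak:
                    out.append(v)
            elif v.support < threshold:
                out.append(v)
        return out

    def clade(self, node):
        return node.leaf_names()

    def copy(self):
        """Deep copy preserving node ids and supports."""
        def rec(n, parent):
            m = Node(id=n.id, name=n.name, length=n.length)
            m.support = n.support
            m.parent = parent
            m.children = [rec(ch, m) for ch in n.children]
            return m

        return GeneTree(rec(self.root, None), self.species_of)

    def newick(self, with_support=True, with_length=False):
        return _write_newick(self.root, with_support=with_support,
                             with_length=with_length)

    def height(self):
        """Height of the tree: the maximum number of ancestors of any node."""
        def rec(n):
            return 1 + max((rec(c) for c in n.children), default=-1)

        return rec(self.root)

    def __len__(self):
        return len(self.postorder())


# -- functional interface -------------------------------------------------


def parse_dated_species_tree(text, dates=None, tol=1e-6):
    """Parse a newick species tree and assign node ages.

    Without a date table, branch lengths must be ultrametric within ``tol``
    and ages are recovered as ``height - depth``.  A ``dates`` mapping
    (node label -> age) overrides branch lengths entirely.
    """
    return DatedSpeciesTree.from_newick(text, dates=dates, tol=tol)


def parse_gene_tree(text, mapping=None, separator="_", species_names=None,
                    support_dialect="label"):
    return GeneTree.from_newick(text, mapping=mapping, separator=separator,
                                species_names=species_names,
                                support_dialect=support_dialect)


def subdivide(species_tree, tol=1e-9):
    """Build the time-sliced subdivision of a dated species tree."""
    return SubdividedSpeciesTree(species_tree, tol=tol)


def weak_edges(gene_tree, threshold, missing_weak=False):
    return gene_tree.weak_edges(threshold, missing_weak=missing_weak)
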