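"""Birth–death simulation of gene family histories along a dated species tree.

A single gene lineage enters the species tree at its root and speciates
whenever it reaches an internal species node.  Strictly between species
nodes each live lineage draws a competing-exponential waiting time for a
birth (a duplication, or a transfer towards a uniformly chosen
contemporaneous other species branch) or a death (a loss).  The process
yields the complete gene tree including extinct subtrees; pruning those
gives the observable "true" gene tree, and the events that left a trace in
it form the true history against which inferences are scored.

Event visibility after pruning follows the DTL reconciliation model: a
duplication or transfer survives as such only if both child copies have
extant descendants; a transfer whose donor-side copy died out entirely is a
composite TL (one transfer plus one loss); a speciation with one side fully
extinct is an SL (one loss); a duplication with one dead side leaves no
trace at all.

Per-family event rates are drawn as in a setting of roughly prokaryotic
gene-family dynamics: loss rate uniform in [0.0010, 0.0018] events per gene
per million years on a species tree scaled to 500 My, a (duplication +
transfer) to loss ratio uniform in [0.5, 1.1], and a duplication share of
the birth rate uniform in [0.70, 1.00].  Families outside the size bounds
(10–100 genes) or with more than 10 visible duplication-plus-transfer
events are resampled from derived sub-seeds up to a retry cap, then flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trees import GeneTree, Node

__all__ = [
    "SimulationParams",
    "SimEvent",
    "TrueEvent",
    "TrueHistory",
    "DerivedEventCosts",
    "UndefinedCostsError",
    "simulate_family",
    "prune_extinct",
    "derive_event_costs",
    "perturb_nni",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of the simulator; defaults are the reference setting
    described in the module docstring.  Setting ``loss_rate`` / ``dup_rate``
    / ``trans_rate`` explicitly bypasses the random per-family draws, and
    ``height=None`` keeps the species tree's own time scale."""

    height: float | None = 500.0
    loss_rate_range: tuple = (0.0010, 0.0018)
    birth_loss_ratio_range: tuple = (0.5, 1.1)
    dup_fraction_range: tuple = (0.70, 1.00)
    size_bounds: tuple = (10, 100)
    max_dup_transfer: int = 10
    max_retries: int = 50
    loss_rate: float | None = None
    dup_rate: float | None = None
    trans_rate: float | None = None

    def draw_rates(self, rng):
        if self.loss_rate is not None:
            loss = self.loss_rate
            dup = self.dup_rate or 0.0
            trans = self.trans_rate or 0.0
            return dup, trans, loss
        loss = rng.uniform(*self.loss_rate_range)
        birth = loss * rng.uniform(*self.birth_loss_ratio_range)
        dup = birth * rng.uniform(*self.dup_fraction_range)
        return dup, birth - dup, loss


@dataclass
class SimEvent:
    """Raw simulated event. ``branch`` is the species branch (lower-endpoint
    node name) on which it happened; transfers also carry the receiver."""

    kind: str  # "speciation" | "D" | "T" | "L"
    time: float
    branch: str
    receiver: str | None = None
    lineage: int = 0


@dataclass
class TrueEvent:
    """Event visible in the pruned true gene tree."""

    kind: str  # "S" | "D" | "T" | "TL" | "SL"
    clade: frozenset  # extant gene leaves of the lineage carrying the event
    branch: str  # species branch of the event (donor branch for T/TL)
    receiver: str | None = None  # receiver branch for T/TL
    loss_branch: str | None = None  # lost species branch for SL
    time: float = 0.0


class _SimNode(Node):
    __slots__ = ("kind", "branch", "receiver", "lineage", "extinct")

    def __init__(self, kind, time, branch, lineage):
        super().__init__()
        self.kind = kind  # "spec" | "D" | "T" | "loss" | "leaf"
        self.time = time
        self.branch = branch
        self.receiver = None
        self.lineage = lineage
        self.extinct = kind == "loss"


@dataclass
class TrueHistory:
    """Ground truth of one simulated gene family."""

    complete_root: object
    true_tree: GeneTree | None
    events: list = field(default_factory=list)  # all SimEvents
    true_events: list = field(default_factory=list)  # visible TrueEvents
    n_duplications: int = 0
    n_transfers: int = 0  # T plus TL
    n_losses: int = 0  # SL plus TL
    rates: tuple = (0.0, 0.0, 0.0)
    seed: int = 0
    flags: list = field(default_factory=list)

    @property
    def ok(self):
        return not self.flags

    def event_keys(self):
        """Location keys per event kind, for accuracy scoring."""
        from .evaluate import true_event_keys

        return true_event_keys(self)


@dataclass(frozen=True)
class DerivedEventCosts:
    dup: float
    trans: float
    loss: float


class UndefinedCostsError(ValueError):
    """No visible event at all: the cost formula is undefined."""


class _Simulator:
    def __init__(self, species_tree, dup, trans, loss, rng, scale):
        self.S = species_tree
        self.dup = dup
        self.trans = trans
        self.loss = loss
        self.total = dup + trans + loss
        self.rng = rng
        self.scale = scale
        self.events = []
        self._lineage_counter = 0
        self._leaf_counter = 0
        self._loss_counter = 0

    def time_of(self, node):
        return node.time * self.scale

    def new_lineage(self):
        self._lineage_counter += 1
        return self._lineage_counter

    def alive_branches(self, t, exclude):
        out = []
        for n in self.S.nodes:
            if n.parent is None:
                continue
            if self.time_of(n) < t < self.time_of(n.parent) and n is not exclude:
                out.append(n)
        return out

    def run(self):
        root = self.S.root
        node = _SimNode("spec", self.time_of(root), root.name, 0)
        self.events.append(
            SimEvent("speciation", node.time, root.name, lineage=0))
        node.children = [
            self.evolve(root.children[0], node.time, 0),
            self.evolve(root.children[1], node.time, self.new_lineage()),
        ]
        for ch in node.children:
            ch.parent = node
        return node

    def evolve(self, sp, t_start, lineage):
        """Evolve one gene lineage down the species branch ending at ``sp``,
        starting at time ``t_start``."""
        t_end = self.time_of(sp)
        if self.total > 0:
            t_event = t_start - self.rng.exponential(1.0 / self.total)
        else:
            t_event = -math.inf
        if t_event <= t_end:
            # reached the bottom of the branch without an event
            if sp.is_leaf:
                node = _SimNode("leaf", t_end, sp.name, lineage)
                self._leaf_counter += 1
                node.name = f"g{self._leaf_counter}_{sp.name}"
                return node
            node = _SimNode("spec", t_end, sp.name, lineage)
            self.events.append(
                SimEvent("speciation", t_end, sp.name, lineage=lineage))
            kids = [self.evolve(sp.children[0], t_end, lineage),
                    self.evolve(sp.children[1], t_end, self.new_lineage())]
            node.children = kids
            for ch in kids:
                ch.parent = node
            return node
        r = self.rng.random() * self.total
        if r < self.loss:
            node = _SimNode("loss", t_event, sp.name, lineage)
            self._loss_counter += 1
            node.name = f"LOSS{self._loss_counter}"
            self.events.append(SimEvent("L", t_event, sp.name, lineage=lineage))
            return node
        if r < self.loss + self.dup:
            node = _SimNode("D", t_event, sp.name, lineage)
            self.events.append(SimEvent("D", t_event, sp.name, lineage=lineage))
            kids = [self.evolve(sp, t_event, lineage),
                    self.evolve(sp, t_event, self.new_lineage())]
        else:
            receivers = self.alive_branches(t_event, sp)
            if not receivers:
                # no contemporaneous branch: the transfer cannot happen;
                # the lineage simply continues (possible only on degenerate
                # single-branch segments)
                return self.evolve(sp, t_event, lineage)
            recv = receivers[self.rng.integers(len(receivers))]
            node = _SimNode("T", t_event, sp.name, lineage)
            node.receiver = recv.name
            self.events.append(SimEvent("T", t_event, sp.name,
                                        receiver=recv.name, lineage=lineage))
            kids = [self.evolve(sp, t_event, lineage),
                    self.evolve(recv, t_event, self.new_lineage())]
        node.children = kids
        for ch in kids:
            ch.parent = node
        return node


def _species_children(species_tree, name):
    node = species_tree.node_by_key[name]
    return [ch.name for ch in node.children]


def _extract_true(sim_root, species_tree):
    """Prune extinct subtrees and collect the visible events.

    Returns ``(true_root_or_None, true_events)`` where the true root is a
    plain :class:`Node` tree whose leaves keep their gene labels.
    """
    events = []

    def clade_of(node):
        return node.leaf_names()

    def rec(n):
        # returns (Node or None, path events above the returned node)
        if n.kind == "leaf":
            m = Node(name=n.name)
            return m, []
        if n.kind == "loss":
            return None, None
        kids = [rec(ch) for ch in n.children]
        alive = [(sub, pev) for sub, pev in kids if sub is not None]
        if not alive:
            return None, None
        if len(alive) == 1:
            sub, pev = alive[0]
            extra = []
            if n.kind == "spec":
                # one side fully extinct: SL, loss in the dead child branch
                dead_idx = 0 if kids[0][0] is None else 1
                children = _species_children(species_tree, n.branch)
                # child branch order in the species tree matches the order
                # in which the simulator split the lineage
                lost = children[dead_idx]
                extra = [("SL", n.branch, lost, n.time)]
            elif n.kind == "T" and kids[0][0] is None:
                # only the transferred copy survives: composite TL
                extra = [("TL", n.branch, n.receiver, n.time)]
            # dead-sided duplications and transfers whose transferred copy
            # died leave no visible trace
            return sub, extra + pev
        (sub1, pev1), (sub2, pev2) = alive
        m = Node(name=None)
        m.children = [sub1, sub2]
        sub1.parent = m
        sub2.parent = m
        for sub, pev in alive:
            _attach_path(sub, pev, events)
        kind = {"spec": "S", "D": "D", "T": "T"}[n.kind]
        m_meta = (kind, n.branch, n.receiver, n.time)
        _pending.append((m, m_meta))
        return m, []

    _pending = []
    top, pev_root = rec(sim_root)
    if top is None:
        return None, []
    _attach_path(top, pev_root, events)
    # terminal events of retained internal nodes
    for node, (kind, branch, receiver, time) in _pending:
        events.append(TrueEvent(kind, node.leaf_names(), branch,
                                receiver=receiver, time=time))
    return top, events


def _attach_path(node, path_events, out):
    """Path events above ``node`` belong to the lineage ending at it."""
    clade = node.leaf_names()
    for kind, branch, other, time in path_events:
        if kind == "SL":
            out.append(TrueEvent("SL", clade, branch, loss_branch=other,
                                 time=time))
        else:  # TL
            out.append(TrueEvent("TL", clade, branch, receiver=other,
                                 time=time))


def prune_extinct(root, extinct=None):
    """True gene tree obtained by removing extinct subtrees and suppressing
    the resulting single-child nodes; ``None`` when everything died.

    ``extinct`` is an optional set of leaf names to treat as dead; by
    default the simulator's own extinction flags are used.
    """
    def is_dead(n):
        if extinct is not None:
            return n.name in extinct
        return getattr(n, "extinct", False)

    def rec(n):
        if n.is_leaf:
            return None if is_dead(n) else Node(name=n.name)
        alive = [k for k in (rec(ch) for ch in n.children) if k is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        m = Node(name=None)
        m.children = alive
        for ch in alive:
            ch.parent = m
        return m

    return rec(root)


def _finish_tree(root, species_tree, default_support=None):
    """Wrap a pruned root into a GeneTree with suffix species mapping."""
    for i, n in enumerate(root.postorder()):
        n.id = i
        if n.children:
            n.support = default_support if n.parent is not None else None
    species_of = {}
    for leaf in root.leaves():
        species_of[leaf.name] = leaf.name.rsplit("_", 1)[-1]
    return GeneTree(root, species_of)


def simulate_family(species_tree, params=None, seed=0):
    """Simulate one gene family; resample (derived sub-seeds) while the
    retention filters reject it, then flag."""
    params = params or SimulationParams()
    base = int(seed)
    history = None
    for attempt in range(params.max_retries + 1):
        sub_seed = (base * 1_000_003 + attempt) % (2**31)
        history = _simulate_once(species_tree, params, sub_seed)
        if history.ok:
            return history
    return history


def _simulate_once(species_tree, params, seed):
    rng = np.random.default_rng(seed)
    dup, trans, loss = params.draw_rates(rng)
    scale = 1.0
    if params.height is not None and species_tree.height > 0:
        scale = params.height / species_tree.height
    sim = _Simulator(species_tree, dup, trans, loss, rng, scale)
    complete = sim.run()
    true_root, true_events = _extract_true(complete, species_tree)

    history = TrueHistory(complete_root=complete, true_tree=None,
                          events=sim.events, true_events=true_events,
                          rates=(dup, trans, loss), seed=seed)
    if true_root is None:
        history.flags.append("extinct")
        return history
    history.true_tree = _finish_tree(true_root, species_tree)
    history.n_duplications = sum(1 for e in true_events if e.kind == "D")
    history.n_transfers = sum(1 for e in true_events if e.kind in ("T", "TL"))
    history.n_losses = sum(1 for e in true_events if e.kind in ("SL", "TL"))

    n_genes = len(history.true_tree.leaves())
    lo, hi = params.size_bounds
    if n_genes < lo:
        history.flags.append("too_small")
    elif n_genes > hi:
        history.flags.append("too_large")
    if history.n_duplications + history.n_transfers > params.max_dup_transfer:
        history.flags.append("too_many_dup_transfer")
    return history


def derive_event_costs(history, base=math.e):
    """Event costs from true-history totals: ``cost_E = log(total / n_E)``
    with ``n_E`` replaced by 0.1 when the kind never occurred; ``total`` is
    the number of visible duplications, transfers and losses."""
    d, t, l = history.n_duplications, history.n_transfers, history.n_losses
    total = d + t + l
    if total <= 0:
        raise UndefinedCostsError("history contains no visible D/T/L event")

    def one(count):
        return math.log(total / (count if count else 0.1), base)

    return DerivedEventCosts(dup=one(d), trans=one(t), loss=one(l))


def perturb_nni(gene_tree, n_moves, rng, weak_support=10.0,
                strong_support=95.0):
    """Topological error model: apply ``n_moves`` random NNIs to a copy of
    the tree, giving rearranged edges a weak support and all others a strong
    one.  Emulates the weakly supported wrong edges of an estimated gene
    tree without simulating sequences."""
    from .search import NniMove

    g = gene_tree.copy()
    for v in g.internal_edges():
        v.support = strong_support
    for _ in range(n_moves):
        candidates = g.internal_edges()
        if not candidates:
            break
        v = candidates[rng.integers(len(candidates))]
        choice = int(rng.integers(2))
        NniMove(v.id, choice).apply(g)
        v.support = weak_support
    return g
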