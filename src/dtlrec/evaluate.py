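"""Accuracy of inferred gene trees and reconciliations against ground truth.

Two measures are provided:

* the rooted Robinson–Foulds distance — the size of the symmetric difference
  of the two trees' non-trivial clade sets;
* per-event-kind true/false positive and false negative counts.  An event is
  a true positive when its kind, its gene-tree location (the clade of the
  gene node carrying it) and its species-tree location all agree; a transfer
  must additionally name both the correct donor and the correct receiver
  species branch.  True negatives are not defined for this task.

Predicted events live on the subdivided species tree; their vertices are
projected back to the original species branch (the lower endpoint of the
edge hosting the vertex) before matching, since the true history is recorded
on the species tree itself.  Losses are keyed by the lost species branch and
the clade of the gene lineage above which the loss occurred; this convention
is symmetric between predicted and true events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "ComparisonError",
    "EventMatchReport",
    "rf_distance",
    "clade_set",
    "reconciliation_event_keys",
    "true_event_keys",
    "match_events",
]


class ComparisonError(ValueError):
    """Trees or histories are not comparable."""


def _root_of(tree):
    return tree.root if hasattr(tree, "root") else tree


def clade_set(tree):
    """Non-trivial clades (internal, non-root) as frozensets of leaf names."""
    root = _root_of(tree)
    out = set()
    for n in root.postorder():
        if n.children and n.parent is not None:
            out.add(n.leaf_names())
    return out


def rf_distance(tree1, tree2):
    """Rooted Robinson–Foulds distance between two binary trees on the same
    leaf set."""
    r1, r2 = _root_of(tree1), _root_of(tree2)
    if r1.leaf_names() != r2.leaf_names():
        raise ComparisonError("trees have different leaf sets")
    return len(clade_set(r1) ^ clade_set(r2))


@dataclass
class EventMatchReport:
    """TP/FP/FN per event kind plus combined rollups."""

    tp: dict = field(default_factory=dict)
    fp: dict = field(default_factory=dict)
    fn: dict = field(default_factory=dict)
    rf: int | None = None

    KINDS = ("D", "T", "L")

    def rollup(self, kinds):
        return (sum(self.tp[k] for k in kinds),
                sum(self.fp[k] for k in kinds),
                sum(self.fn[k] for k in kinds))

    @property
    def dt(self):
        return self.rollup(("D", "T"))

    @property
    def dtl(self):
        return self.rollup(self.KINDS)

    def as_dict(self):
        d = {k: {"tp": self.tp[k], "fp": self.fp[k], "fn": self.fn[k]}
             for k in self.KINDS}
        tp, fp, fn = self.dtl
        d["DTL"] = {"tp": tp, "fp": fp, "fn": fn}
        if self.rf is not None:
            d["rf"] = self.rf
        return d


def reconciliation_event_keys(reconciliation, gene_tree, subdivision):
    """Location keys of the D, T and L events of a reconciliation.

    Keys: ``("D", clade, branch)``, ``("T", clade, donor, receiver)`` and
    ``("L", clade, branch)``; a TL step contributes one transfer key and one
    loss key on the donor branch, an SL one loss key on the lost child
    branch.
    """
    keys = []
    for uid, seq in reconciliation.alpha.items():
        node = gene_tree.node_by_id[uid]
        clade = node.leaf_names()
        for i, (vid, ev) in enumerate(seq):
            x = subdivision.vertices[vid]
            if ev == "D":
                keys.append(("D", clade, x.branch))
            elif ev == "T":
                # the receiver is where the transferred child starts
                recv_vid = _transfer_receiver(reconciliation, gene_tree,
                                              node, vid)
                keys.append(("T", clade, x.branch,
                             subdivision.vertices[recv_vid].branch))
            elif ev == "TL":
                nxt = seq[i + 1][0]
                keys.append(("T", clade, x.branch,
                             subdivision.vertices[nxt].branch))
                keys.append(("L", clade, x.branch))
            elif ev == "SL":
                nxt = seq[i + 1][0]
                lost = next(ch.id for ch in x.children if ch.id != nxt)
                keys.append(("L", clade, subdivision.vertices[lost].branch))
    return keys


def _transfer_receiver(reconciliation, gene_tree, node, donor_vid):
    for ch in node.children:
        first = reconciliation.alpha[ch.id][0][0]
        if first != donor_vid:
            return first
    # both children start at the donor vertex: degenerate, should not occur
    raise AssertionError("transfer without a displaced child")


def true_event_keys(history):
    """Location keys of the visible events of a simulated true history, in
    the same format as :func:`reconciliation_event_keys`."""
    keys = []
    for ev in history.true_events:
        if ev.kind == "D":
            keys.append(("D", ev.clade, ev.branch))
        elif ev.kind == "T":
            keys.append(("T", ev.clade, ev.branch, ev.receiver))
        elif ev.kind == "TL":
            keys.append(("T", ev.clade, ev.branch, ev.receiver))
            keys.append(("L", ev.clade, ev.branch))
        elif ev.kind == "SL":
            keys.append(("L", ev.clade, ev.loss_branch))
    return keys


def match_events(predicted_keys, true_keys, rf=None):
    """Multiset matching of predicted against true event keys.

    ``predicted_keys``/``true_keys`` are sequences as produced by
    :func:`reconciliation_event_keys` and :func:`true_event_keys`.
    """
    report = EventMatchReport(rf=rf)
    pred = Counter(predicted_keys)
    true = Counter(true_keys)
    for kind in EventMatchReport.KINDS:
        p = Counter({k: v for k, v in pred.items() if k[0] == kind})
        t = Counter({k: v for k, v in true.items() if k[0] == kind})
        tp = sum((p & t).values())
        report.tp[kind] = tp
        report.fp[kind] = sum(p.values()) - tp
        report.fn[kind] = sum(t.values()) - tp
    return report


def compare(reconciliation, gene_tree, subdivision, history,
            with_rf=True):
    """Score a reconciliation of ``gene_tree`` against a simulated history."""
    if history.true_tree is None:
        raise ComparisonError("history has no surviving gene tree")
    rf = None
    if with_rf:
        rf = rf_distance(gene_tree, history.true_tree)
    return match_events(
        reconciliation_event_keys(reconciliation, gene_tree, subdivision),
        true_event_keys(history),
        rf=rf,
    )
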