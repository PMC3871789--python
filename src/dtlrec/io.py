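"""Readers and writers for the text formats used by the tool.

Everything is plain UTF-8 text with LF line endings: newick for trees, TSV
for tables (reconciliation steps, node dates, leaf-species maps), JSON for
summaries and simulated histories.  Writers prepend a provenance comment
naming the tool version, the subcommand configuration and the seed, so every
output is self-describing; costs are printed with fixed 6-decimal formatting
for reproducible diffs.
"""

from __future__ import annotations

import json

from . import __version__
from .reconcile import Reconciliation

__all__ = [
    "read_date_table",
    "read_leaf_map",
    "provenance_header",
    "write_reconciliation_tsv",
    "read_reconciliation_tsv",
    "write_summary_json",
    "write_history_json",
    "read_history_json",
    "annotated_newick",
]

_EVENT_OUT = {"E": "EMPTY"}
_EVENT_IN = {"EMPTY": "E"}


def read_date_table(path):
    """Node-date TSV: ``node_label<TAB>age`` per line; '#' comments allowed."""
    dates = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, age = line.split("\t")
            dates[label] = float(age)
    return dates


def read_leaf_map(path):
    """Leaf-map TSV: ``gene_leaf<TAB>species`` per line."""
    mapping = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, species = line.split("\t")
            mapping[gene] = species
    return mapping


def provenance_header(config=None, seed=None, comment="#"):
    parts = [f"dtlrec {__version__}"]
    if config:
        parts.append(" ".join(f"{k}={v}" for k, v in sorted(config.items())))
    if seed is not None:
        parts.append(f"seed={seed}")
    return f"{comment} " + " | ".join(parts)


def write_reconciliation_tsv(path, reconciliation, gene_tree, subdivision,
                             config=None, seed=None):
    """One row per reconciliation step: gene node, step index, species
    vertex, event (C/S/D/T/EMPTY/SL/TL)."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        fh.write("gene_node\tstep_index\tspecies_vertex\tevent\n")
        for uid in sorted(reconciliation.alpha):
            node = gene_tree.node_by_id[uid]
            label = node.name if node.is_leaf else f"node{uid}"
            for i, (vid, ev) in enumerate(reconciliation.alpha[uid]):
                vname = subdivision.vertices[vid].name
                fh.write(f"{label}\t{i}\t{vname}\t{_EVENT_OUT.get(ev, ev)}\n")


def read_reconciliation_tsv(path):
    """Read the step table back as ``{gene_node: [(species_vertex, event)]}``."""
    steps = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_node"):
                continue
            label, idx, vname, ev = line.split("\t")
            steps.setdefault(label, []).append((vname, _EVENT_IN.get(ev, ev)))
    return steps


def write_summary_json(path, summary, config=None, seed=None):
    doc = {"tool": "dtlrec", "version": __version__}
    if config:
        doc["config"] = {k: str(v) for k, v in sorted(config.items())}
    if seed is not None:
        doc["seed"] = seed
    doc.update(summary)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def annotated_newick(gene_tree, reconciliation, subdivision):
    """Gene-tree newick with NHX-style per-node event annotations."""
    from .trees import _write_newick

    def decorate(node):
        seq = reconciliation.alpha.get(node.id)
        if not seq:
            return ""
        events = "-".join(ev for _, ev in seq)
        vertex = subdivision.vertices[seq[-1][0]].name
        return f"[&&NHX:events={events}:vertex={vertex}]"

    return _write_newick(gene_tree.root, with_support=True, with_length=False,
                         decorate=decorate)


def _event_doc(ev):
    doc = {"kind": ev.kind, "time": ev.time, "branch": ev.branch,
           "lineage": ev.lineage}
    if ev.receiver is not None:
        doc["receiver"] = ev.receiver
    return doc


def write_history_json(path, history, config=None, seed=None):
    """Simulated history: params echo, event list, complete + true newick."""
    from .trees import _write_newick

    doc = {
        "tool": "dtlrec",
        "version": __version__,
        "seed": history.seed,
        "rates": {"dup": f"{history.rates[0]:.6f}",
                  "trans": f"{history.rates[1]:.6f}",
                  "loss": f"{history.rates[2]:.6f}"},
        "flags": history.flags,
        "totals": {"D": history.n_duplications, "T": history.n_transfers,
                   "L": history.n_losses},
        "events": [_event_doc(e) for e in history.events],
        "true_events": [
            {"kind": e.kind, "clade": sorted(e.clade), "branch": e.branch,
             "receiver": e.receiver, "loss_branch": e.loss_branch,
             "time": e.time}
            for e in history.true_events
        ],
        "complete_tree": _write_newick(history.complete_root,
                                       with_length=False),
        "true_tree": (history.true_tree.newick(with_support=False)
                      if history.true_tree is not None else None),
    }
    if config:
        doc["config"] = {k: str(v) for k, v in sorted(config.items())}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_history_json(path):
    with open(path) as fh:
        return json.load(fh)
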