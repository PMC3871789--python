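"""Model/Results interface to DTL reconciliation with NNI correction.

``DTLReconciliationModel`` bundles an instance — a support-annotated gene
tree, a dated species tree and the event costs — and ``fit`` performs the
parsimony optimisation: a plain most parsimonious reconciliation when the
weak-edge threshold is 0, otherwise an NNI hill climb over weak edges
followed by the reconciliation of the rearranged tree.  The returned
``ReconciliationResults`` carries the optimal tree, its reconciliation, the
event counts and the search trace, and renders a plain-text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reconcile import EventCosts, backtrack, fill_cost_matrix
from .search import SearchTrace, hill_climb
from .trees import parse_dated_species_tree, parse_gene_tree, subdivide

__all__ = ["DTLReconciliationModel", "ReconciliationResults"]


class DTLReconciliationModel:
    """Parsimony reconciliation model for one gene family.

    Parameters
    ----------
    gene_tree : GeneTree
        Rooted binary gene tree with supports on internal edges.
    species_tree : DatedSpeciesTree
        Dated rooted binary species tree.
    costs : EventCosts, optional
        Duplication/transfer/loss (and optional speciation) costs; defaults
        to the ``hogenom`` profile (3.5, 3, 1).
    threshold : float, optional
        Support threshold below which an edge is weak and may be rearranged;
        0 disables the search entirely.
    missing_support_weak : bool, optional
        Treat edges without a support value as weak (default: strong).
    """

    def __init__(self, gene_tree, species_tree, costs=None, threshold=0.0,
                 missing_support_weak=False):
        self.gene_tree = gene_tree
        self.species_tree = species_tree
        self.costs = costs or EventCosts.hogenom()
        self.threshold = float(threshold)
        self.missing_support_weak = missing_support_weak
        self.subdivision = subdivide(species_tree)
        # fail fast on unmapped leaves
        for leaf in gene_tree.leaves():
            sp = gene_tree.species_of[leaf.name]
            if sp not in species_tree.leaves:
                from .trees import GeneMappingError

                raise GeneMappingError(
                    f"gene leaf {leaf.name} maps to unknown species {sp!r}")

    @classmethod
    def from_files(cls, gene_path, species_path, dates_path=None,
                   mapping_path=None, separator="_", **kwargs):
        """Build a model from newick files (and optional TSV tables)."""
        from . import io as _io

        dates = _io.read_date_table(dates_path) if dates_path else None
        mapping = _io.read_leaf_map(mapping_path) if mapping_path else None
        with open(species_path) as fh:
            species = parse_dated_species_tree(fh.read(), dates=dates)
        with open(gene_path) as fh:
            gene = parse_gene_tree(fh.read(), mapping=mapping,
                                   separator=separator,
                                   species_names=set(species.leaves))
        return cls(gene, species, **kwargs)

    def fit(self, naive=False):
        """Run the reconciliation (and the NNI search when threshold > 0)."""
        matrix = fill_cost_matrix(self.gene_tree, self.subdivision, self.costs)
        initial_cost = matrix.optimal_cost()
        if self.threshold > 0:
            tree, reconciliation, trace = hill_climb(
                self.gene_tree, self.subdivision, self.costs, self.threshold,
                naive=naive, missing_weak=self.missing_support_weak)
        else:
            tree = self.gene_tree.copy()
            reconciliation = backtrack(matrix)
            trace = SearchTrace(initial_cost=initial_cost,
                                final_cost=initial_cost)
        return ReconciliationResults(model=self, gene_tree_=tree,
                                     reconciliation=reconciliation,
                                     trace=trace,
                                     initial_cost=initial_cost,
                                     cost=trace.final_cost)


@dataclass
class ReconciliationResults:
    """Fitted reconciliation: optimal tree, events, and search diagnostics."""

    model: DTLReconciliationModel
    gene_tree_: object
    reconciliation: object
    trace: SearchTrace
    initial_cost: float
    cost: float

    @property
    def duplications(self):
        return self.reconciliation.duplications

    @property
    def transfers(self):
        return self.reconciliation.transfers

    @property
    def losses(self):
        return self.reconciliation.losses

    def compare_to(self, history):
        """Accuracy report against a simulated true history."""
        from .evaluate import compare

        return compare(self.reconciliation, self.gene_tree_,
                       self.model.subdivision, history)

    def summary(self):
        c = self.model.costs
        lines = [
            "DTL reconciliation results",
            "==========================",
            f"gene leaves:        {len(self.gene_tree_.leaves())}",
            f"species leaves:     {len(self.model.species_tree.leaves)}",
            f"subdivision size:   {len(self.model.subdivision)}",
            f"costs (dup/trans/loss/spec): "
            f"{c.dup:g}/{c.trans:g}/{c.loss:g}/{c.spec:g}",
            f"weak-edge threshold: {self.model.threshold:g}",
            "--------------------------",
            f"initial cost:       {self.initial_cost:.6f}",
            f"final cost:         {self.cost:.6f}",
            f"duplications:       {self.duplications}",
            f"transfers:          {self.transfers}",
            f"losses:             {self.losses}",
            f"NNI evaluated:      {self.trace.n_evaluations}",
            f"NNI accepted:       {self.trace.n_accepted}",
            f"columns recomputed: {self.trace.n_columns_recomputed}",
        ]
        return "\n".join(lines)
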