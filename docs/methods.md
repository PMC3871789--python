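# Methods

## Reconciliation model

A reconciliation maps each node `u` of a rooted binary gene tree `G` onto an
ordered sequence of vertices of the subdivided species tree `S'`. Exactly
one atomic event holds at each step: the last step of a sequence is a
contemporaneous leaf match (C), a speciation (S), a duplication (D) or a
transfer (T); every earlier step is a free descent through an artificial
vertex (∅), a speciation with loss of one descendant copy (SL), or a
transfer with loss of the non-transferred copy (TL). Both composite events
bundle a loss with the event that makes it observable, which is what makes
a recursive optimisation possible without restricting the model. The cost
of a reconciliation is `d·δ + t·τ + l·λ`, where TL contributes to both `t`
and `l` and SL to `l`. Speciations cost σ = 0 by default; σ is a
first-class parameter and, when nonzero, also enters the composite SL
(σ + λ) and is counted for S and SL events alike.

An optimal sequence never contains two consecutive TL steps: two transfers
in a row with immediate loss of both donor copies can always be replaced by
a single TL at lower cost. The DP exploits this by computing, per cell
`(u, x)`, first the cheapest non-TL scenario `c̄(u, x)` and then completing
`c(u, x) = min(c̄(u, x), τ + λ + min_{y ≠ x, same slice} c̄(u, y))`.

## Dated species tree and subdivision

Node ages are taken from ultrametric branch lengths (age = height − depth)
with an ultrametricity tolerance of 1e-6, or from an explicit node-date
table that overrides lengths entirely; only the induced order of internal
nodes matters to the model, not absolute ages. Parent ages must strictly
exceed child ages. Distinct internal nodes *may* share an age, in which
case they share a time slice and no artificial vertex is inserted between
them; age equality is decided with a tolerance of 1e-9. For every internal
age `t` and every edge strictly spanning `t`, one artificial single-child
vertex is inserted at `t`, so `|V(S')| ≤ |V(S)|²`. Vertices are indexed in
slice-major order (increasing time), which also serves as the deterministic
tie-break order.

## Dynamic program

The matrix is filled one gene-tree column at a time in postorder; within a
column, slices are visited in increasing time. This satisfies every
dependency of the recurrences (children's columns are complete, a column's
own lower slices precede higher ones, and `c̄` precedes TL within a slice)
and computes exactly the same cells as a slice-major sweep; the column
routine is reused verbatim by the incremental NNI update, so recomputed
columns are bit-for-bit reproducible. Transfer scenarios use the slice's
best and second-best child costs (the second-best when the best sits at the
donor itself), so the fill costs O(|S'|·|G|) cell updates in total rather
than a quadratic per-slice scan; a test checks this summary against the
naive scan.

Ties are broken deterministically: event priority C > S > D > T > ∅ > SL >
TL, then the lower gene-child index (for the two child-to-species
assignments of S, and "first child stays" for T), then the lowest vertex id
(slice order). The root is placed at the lowest-id optimal vertex.
Infeasible cells hold IEEE infinity — float arithmetic saturates, so sums
involving impossible scenarios remain impossible without a sentinel
constant. Backtracking replays the stored per-cell decisions; after a TL
step the continuation is the non-TL decision of the receiver cell, which is
what guarantees the no-consecutive-TL invariant in every output.

## NNI search

Only internal edges with support strictly below the threshold `t` are
candidates; edges lacking a support value are treated as strong unless
explicitly configured otherwise, so an unannotated input is never
rearranged by accident. Weak edges are visited in postorder; both
alternatives of an edge are evaluated and the cheaper one is adopted only
on a strict cost decrease (ties are rejected, guaranteeing termination);
after an acceptance the scan restarts from the first weak edge, since a
previously unhelpful edge can become improving after a nearby change. The
rearranged edge keeps its (weak) support and every other edge keeps its
own, as an NNI leaves all other bipartitions intact.

An NNI around `(w, v)` changes descendant sets only for `v` and its
ancestors, so only those columns are recomputed, bottom-up. From `w`
upward, if the old column dominates the new one everywhere (`old ≤ new` for
every vertex), no higher column — hence the optimal cost — can improve, and
the candidate is rejected without further work; dominance propagates
upward because every recurrence is monotone in the child costs it reads.
Rejection via dominance is conservative (the full cost is provably not
lower), and a completed ascent yields the exact matrix of the new tree,
sharing the untouched columns. The naive mode (full refill per candidate)
is retained behind a flag and must reach identical trees and costs under
the identical visit order; the test suite asserts this equivalence.

No caching is attempted across accepted moves beyond the column sharing
described above: there is no safe criterion for skipping the re-test of an
edge that failed earlier, so the search conservatively re-examines all weak
edges after each acceptance.

## Simulator

One gene lineage enters at the species root and splits at every species
node it reaches. Strictly inside a branch, each live lineage draws
competing exponential waiting times for duplication, transfer and loss
(Gillespie); a transfer picks its receiver uniformly among the species
branches alive at that instant, donor excluded — the receiver distribution
is otherwise unconstrained, and uniform is the minimal assumption. At a
duplication or speciation one child keeps the parent's lineage identity;
this makes per-lineage event counts along a branch Poisson with mean
rate × length, which the calibration tests verify by chi-square goodness of
fit.

Default study conditions: the species tree is rescaled to a height of 500
million years; per family, the loss rate is uniform in [0.0010, 0.0018]
events/gene/My, the (duplication+transfer):loss ratio uniform in
[0.5, 1.1], and the duplication share of the birth rate uniform in
[0.70, 1.00]. Families are retained when they hold 10–100 genes and at most
10 visible duplication-plus-transfer events; rejected draws are resampled
from derived sub-seeds up to a retry cap, then flagged. All randomness
flows from a single integer seed and identical seeds give byte-identical
histories.

Visible ("true") events are defined by the trace the process leaves in the
pruned gene tree, mirroring the reconciliation model: a duplication or
transfer node counts as D or T only when both child copies have extant
descendants; a transfer whose donor-side copy left none is a TL (one
transfer, one loss); a speciation with one side fully extinct is an SL (one
loss); a duplication with one dead side is invisible. Event costs derived
from a history are `log(total/n_E)` per kind (total = visible D+T+L,
`n_E` replaced by 0.1 for a kind that never occurred); the logarithm base
is configurable and defaults to natural log — only cost *ratios* matter to
the parsimony optimum, so the base choice rescales without reordering
optima.

The "noisy gene tree" used in end-to-end experiments is a purely
topological error model: 1–3 random NNIs applied to the true tree, the
rearranged edges marked with support 10 and all others 95, searched at
threshold 50. This emulates weakly supported wrong edges without simulating
sequences; it does **not** reproduce branch-length effects, model
misspecification, or the support distributions of real bootstrap analyses,
so passing recovery tests demonstrate the search's behaviour under its own
assumptions, not field performance on real alignments.

The scaled-down recovery study (tests and `scripts/acceptance.py`) runs 100
families over a random 10-leaf species tree with a minimum family size of 4
(proportional to the reference setting of 10 genes over 37 species);
per-family event costs are derived from the family's own true history, with
the default (3.5, 3, 1) profile as fallback for event-free families.

## Evaluation

The Robinson–Foulds distance is the rooted-tree convention: the symmetric
difference of the two trees' non-trivial clade sets. Event matching
projects predicted events from subdivision vertices back to original
species branches (an artificial vertex reports the branch it subdivides)
and compares multisets of location keys: a duplication matches on (gene
clade, species branch); a transfer on (gene clade, donor branch, receiver
branch) — both ends must be right; a loss on (gene clade above the loss,
lost species branch). Gene-tree locations are identified by leaf-label
clades, so node numbering differences between predicted and true trees are
immaterial. True negatives are not defined for this task and are not
reported. The loss key is this package's documented convention; other
implementations may attribute losses differently.

## Known limitations

Gene and species trees must be rooted and binary; no rerooting or polytomy
resolution is attempted. Exactly one most parsimonious reconciliation is
returned (deterministically), with no enumeration of co-optimal solutions —
accuracy measured against a single MPR is therefore pessimistic when many
exist. The search explores NNI neighbourhoods only; histories whose
correction requires SPR-scale moves will stop at a local optimum. Transfers
may land on any contemporaneous branch, including descendants of the donor
lineage. Sequence evolution and likelihood-based gene-tree inference are
out of scope.
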