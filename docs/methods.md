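# Methods

## Temporal conventions

All times are ages in Ga (10⁹ years) before present: leaves sit at 0, time
increases into the past, and a chronogram's root age is the age of the last
common ancestor of the sampled species. Input newick trees must be rooted,
binary and ultrametric; branch lengths are durations in Ga. Ultrametricity
is checked to a relative tolerance of 1e-6 of the root-to-leaf depth
(newick round-off is common), after which ages are re-projected to exact
ultrametricity by setting each node's age to its mean path length to its
descendant leaves. Internal nodes may carry 95% credibility intervals as
bracketed comments `[&ci={low,high}]`; a node's *working date* is the CI
midpoint when an interval is present and the point age otherwise. The
reconciliation itself always runs on point ages; working dates enter only
when events are dated.

Children are canonically ordered by smallest descendant leaf label and
unnamed internal nodes are labelled `n1, n2, …` in deterministic postorder,
so a branch is identified everywhere by the name of its child node.

## Time slicing and the position graph

The chronogram is sliced at its distinct internal-node ages (ties merged
into one boundary, preserving simultaneous divergences rather than
perturbing them); slice *i* is the interval between consecutive boundaries
and records the branches alive throughout it. A *position* is a
(branch, slice) pair. One extra zero-length *root handle* position above
the root (pseudo-slice −1) allows histories that begin with a speciation at
the root divergence; it has no contemporaries and therefore no transfers.

Movement of a single gene lineage between events is priced by shortest
paths over directed arcs:

- descent along the same branch across a boundary — free;
- descent through a divergence into one daughter branch — a
  *speciation-loss*, cost λ (the speciation is free, the pruned daughter is
  a loss);
- a within-slice jump to a different contemporaneous branch — a
  *transfer-loss*, cost τ + λ (the donor copy is lost).

Restricting jumps to branches alive in the same slice is exactly the
no-transfers-to-the-dead rule: only sampled, extant-at-that-time lineages
have positions. All-pairs distances are computed by Dijkstra with
deterministic tie-breaking (positions ordered by slice, then branch name;
strict-improvement relaxation), and predecessor chains let every shortest
path be decomposed back into explicit speciation + loss and
transfer + loss event records.

## The dynamic program

For gene node *u* at position *p*, C(u, p) is the minimum cost of the
subtree rooted at *u* given that *u*'s event happens at *p*; leaf costs are
the movement distance to the species leaf's terminal position. Internal
nodes minimise over speciation (only where the branch ends at a divergence;
children start on the two daughter branches, both pairings tried),
duplication (δ; both children start at *p*) and transfer (τ; one child
stays at *p*, the other starts at any contemporaneous position on another
branch, found with a per-slice min/second-min trick). Every child term is
min over positions q of [movement(p→q) + C(child, q)]. Origination is free:
the answer is the minimum of C(root, ·) over all positions, so the earliest
inferred event is a lower bound on gene age, not an estimate of gene birth.

Backtracking is deterministic: event priority speciation > duplication >
transfer on cost ties, then the canonically first position. The emitted
event list always satisfies total cost = δ·#D + τ·#T + λ·#L (asserted at
fit time); speciations, including those inside speciation-loss steps, are
free and counted as speciation events, which makes a fully congruent
*n*-leaf family yield cost 0 and exactly *n* − 1 speciations. Terminal
leaf matching is not an event. Transfers are recorded with donor and
recipient; summaries and dating place a transfer on its recipient branch
(where the new copy appears), the RecPhyloXML convention.

Complexity is O(P²) per gene node on P = Σᵢ|alive(i)| positions (plus one
O(P²·log P)-ish all-pairs pass per chronogram/cost pair, reusable across
families via a shared `PositionGraph`). A 20-species chronogram gives
P ≈ 200 and ~15 ms per family.

Default costs are δ = 2, τ = 3, λ = 1 — the default operating point of
widely used parsimony reconciliation programs — and are fully configurable.
Chained within-slice jumps are never cheaper than one jump (every
contemporaneous branch is one jump away), so optima are unaffected by the
single-jump arc structure.

## Brute-force oracle

`brute_force_min_cost` re-derives epoch boundaries directly from node ages
and enumerates histories move by move (descend, speciation-loss, jump,
or an S/D/T event resolving a gene node) in plain recursion under a
branch-and-bound budget, sharing none of the position-graph or
shortest-path machinery. Because every cycle-capable move costs at least
τ + λ > 0, the search is finite and complete up to the cost cap; a finite
result is an exact minimum. An optional memo cache stores exact subproblem
minima — a cached value above the caller's remaining budget only certifies
infeasibility at that budget — and the cached and plain searches are
cross-checked in the tests. Intended for instances with ≤5 species and ≤5
gene leaves, where it certifies the dynamic program.

## Synthetic generator

The species tree is pure-birth (Yule): with *k* lineages the next
divergence is Exp(k·b) away (b = 1 per Ga by default, a shape parameter
only, since trees are rescaled); after conditioning on the leaf count the
tree is rescaled so the root sits at `root_age`, default 4.05 Ga, a
standard relaxed-clock age for the last universal common ancestor. No
extinction means every lineage alive at any time survives to the present,
so the generator satisfies no-transfers-to-the-dead by construction — the
same model the reconciler assumes.

Gene families start as one copy at the root divergence and evolve forward
by a per-copy Gillespie process: duplication, transfer and loss at
constant rates per lineage per Ga (defaults r_dup = 0.05,
r_transfer = 0.10, r_loss = 0.05 — a sparse regime in which most events
are recoverable and transfers outnumber duplications, as in real
prokaryotic gene families). Transfers are additive: the donor copy
persists and a new copy starts on a recipient branch drawn uniformly among
contemporaneous branches other than the donor. At each species divergence
every extant copy speciates into both daughters. The observed gene tree is
the genealogy of surviving copies with lost lineages pruned and
unifurcations suppressed, leaves labelled `species|copyN`; a family whose
copies all die is returned with an extinct flag. Every event is logged with
its exact time, branches, copy id and a visibility flag (whether the event
is detectable in the pruned tree: e.g. a transfer whose recipient lineage
died leaves no trace). Identical (tree, config, seed) inputs give
byte-identical outputs.

What the simulator does *not* emulate: gene-tree estimation error
(alignments, model misspecification, low bootstrap support), unsampled or
extinct donor lineages, rate variation across branches or through time,
and replacement transfers (donor loss coincident with transfer arises only
through an independent loss). Passing recovery tests therefore shows the
inference machinery is correct *under its own generative model*, not that
real gene-family histories are recovered at these accuracies.

## Event dating

`branch` mode (the default, matching how reconciliation events are usually
reported) dates a duplication/transfer/loss as the full interval between
its branch's two working dates — down to 0.00 on leaf branches — with the
midpoint as point summary; speciations get their node's working date
exactly. `slice` mode intersects the branch interval with the event's time
slice, exploiting the dated DP's tighter localisation of transfers; it
uses point ages throughout so the intersection is always well formed.
Reported dates round to 2 decimals, half away from zero (2.765 → 2.77).
When only one endpoint of a branch has a CI, the other uses its point age.
The earliest event of a gene is the one with maximum midpoint; ties break
by larger old-bound, then speciation > duplication > transfer > loss, then
branch name.

## Trend summaries

Per-gene totals are defined as loss + duplication + transfer + speciation
counts (the total is always the sum of the four types, never an
independently tallied figure). Midpoint histograms use half-open bins
[low, high) ascending from 0 with the oldest bin closed; bin width defaults
to 0.25 Ga and proportions are of the gene's total events, so each gene's
proportions sum to 1. Genes are ordered by descending earliest-event
midpoint, ties alphabetical.

## Problem sizes used in the tests and acceptance study

Oracle equivalence: 100 seeded instances, 3–5 species, ≤5 gene leaves,
randomised integer cost schemes in the unit tests. Recovery study: one
20-species, 4.05 Ga chronogram; 200 non-extinct families at default rates;
checks are (i) optimum ≤ cost of the true history priced under the same
scheme (the true history is itself a feasible explanation of the observed
tree, so this must hold in every family), (ii) all transfers
time-consistent, (iii) Spearman ≥ 0.8 between visible true and inferred
transfer counts, (iv) ≥99% of branch-matched true events dated within the
reported range. Congruence: 50 seeded 10-species no-event families.
Monte-Carlo rate identity: 1000 six-species families. These sizes keep the
full suite under ten seconds while leaving every estimate comfortably away
from its threshold.

## Known limitations

- One optimal history is reported per family; co-optima are summarised
  only through `reconcile_many` support frequencies over tree sets, not by
  enumerating the full optimum class or amalgamating over a tree
  distribution.
- No transfers to unsampled/extinct lineages, matching the study design
  but understating transfer opportunity on sparsely sampled trees.
- Gene-tree roots are taken as given; no root search.
- The brute-force oracle is exponential and unusable beyond toy sizes —
  by design, as an independent certificate.
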