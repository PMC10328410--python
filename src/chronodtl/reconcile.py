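"""Maximum-parsimony dated DTL reconciliation.

A rooted binary gene tree is embedded into a time-sliced species chronogram
by choosing, for every gene node, a *position* — a (species branch, time
slice) pair — and an event: speciation (S, free, only where the branch ends
in a divergence), duplication (D, cost δ), or horizontal transfer (T, cost
τ, recipient restricted to branches alive in the same slice, which encodes
the no-transfers-to-the-dead rule).  Movement of a single gene lineage
between events is priced by shortest paths over the position graph, whose
arcs are plain descent (free), speciation-loss (λ) and transfer-loss
(τ + λ); gene origination is free anywhere on the tree.  The optimum
minimises δ·#D + τ·#T + λ·#L.

The model object is :class:`DTLReconciliation`; ``fit()`` returns a
:class:`ReconciliationResult` with the cost, the explicit dated-event list
(speciation-loss and transfer-loss arcs decomposed into speciation/loss and
transfer/loss records), per-type counts and a ``summary()`` table.
:func:`brute_force_min_cost` is an independent enumerator used as a
correctness oracle on small instances.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .chronogram import DatedSpeciesTree, TimeSlicedTree, time_slice

__all__ = [
    "CostScheme",
    "GeneTree",
    "PositionGraph",
    "EventRecord",
    "DTLReconciliation",
    "ReconciliationResult",
    "ReconciliationError",
    "reconcile",
    "reconcile_many",
    "brute_force_min_cost",
]

INF = math.inf


class ReconciliationError(ValueError):
    """Raised for gene/species input mismatches."""


@dataclass(frozen=True)
class CostScheme:
    """DTL event costs (speciation and leaf matching are free).

    Defaults δ=2, τ=3, λ=1 follow the default operating point of standard
    parsimony reconciliation software.
    """

    dup: float = 2.0
    transfer: float = 3.0
    loss: float = 1.0

    def __post_init__(self):
        if min(self.dup, self.transfer, self.loss) < 0:
            raise ValueError("event costs must be nonnegative")


# ---------------------------------------------------------------------------
# gene trees


class GeneNode:
    __slots__ = ("label", "children", "species")

    def __init__(self, label: str = "", children: Optional[list] = None):
        self.label = label
        self.children: list[GeneNode] = children or []
        self.species: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GeneTree:
    """Rooted binary gene tree whose leaves map to species-tree leaves.

    Leaf labels map to species either exactly or by the prefix before the
    first ``|`` (multi-copy families are labelled ``species|copyN``).
    """

    def __init__(self, root: Optional[GeneNode]):
        self.root = root
        self._canonicalize()
        self.postorder: list[GeneNode] = []
        if root is not None:
            self._walk(root)
        counter = 0
        for node in self.postorder:
            if not node.is_leaf:
                node.label = f"g{counter}"
                counter += 1

    def _walk(self, node: GeneNode) -> None:
        for c in node.children:
            self._walk(c)
        self.postorder.append(node)

    def _canonicalize(self) -> None:
        def min_leaf(n: GeneNode) -> str:
            while n.children:
                n = min(n.children, key=min_leaf)
            return n.label

        def rec(n: GeneNode) -> None:
            for c in n.children:
                rec(c)
            n.children.sort(key=min_leaf)

        if self.root is not None:
            rec(self.root)

    @property
    def leaves(self) -> list[GeneNode]:
        return [n for n in self.postorder if n.is_leaf]

    @property
    def is_empty(self) -> bool:
        return self.root is None

    @classmethod
    def from_newick(cls, newick_text: str) -> "GeneTree":
        text = (newick_text or "").strip()
        if text in ("", ";"):
            return cls(None)
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )

        def build(dnode: dendropy.Node) -> GeneNode:
            kids = dnode.child_nodes()
            if not kids:
                return GeneNode(label=dnode.taxon.label)
            if len(kids) != 2:
                raise ReconciliationError("gene tree must be binary and rooted")
            return GeneNode(children=[build(k) for k in kids])

        return cls(build(dtree.seed_node))

    def map_to_species(self, tree: DatedSpeciesTree) -> None:
        for leaf in self.leaves:
            sp = leaf.label.split("|", 1)[0]
            if sp not in tree.leaves:
                raise ReconciliationError(
                    f"gene leaf {leaf.label!r} matches no species-tree leaf"
                )
            leaf.species = sp


def as_gene_tree(gene_tree: Union[str, GeneTree]) -> GeneTree:
    if isinstance(gene_tree, GeneTree):
        return gene_tree
    return GeneTree.from_newick(gene_tree)


# ---------------------------------------------------------------------------
# position graph

ROOT_SLICE = -1  # pseudo-slice for the zero-length handle above the root


class PositionGraph:
    """(branch × slice) positions with single-lineage movement costs.

    Arcs: descent along the same branch across a slice boundary (free);
    descent through a divergence into one daughter branch (speciation-loss,
    λ); within-slice jump to a contemporaneous branch (transfer-loss, τ+λ).
    A zero-length *root handle* position above the species root (pseudo-slice
    −1) lets histories begin with a speciation at the root node; it has no
    contemporaries, hence no transfers.  ``M[p, q]`` is the shortest-path
    movement cost, infinite whenever q is not at the same or a later slice.
    """

    def __init__(self, sliced: TimeSlicedTree, costs: CostScheme):
        self.sliced = sliced
        self.costs = costs
        tree = sliced.tree
        self.positions: list[tuple[str, int]] = [(tree.root.name, ROOT_SLICE)]
        for i, edges in enumerate(sliced.alive):
            for e in edges:
                self.positions.append((e, i))
        self.index = {p: k for k, p in enumerate(self.positions)}
        self._build_arcs()
        self._shortest_paths()

    # -- structure ------------------------------------------------------------

    def _build_arcs(self) -> None:
        sliced, tree = self.sliced, self.sliced.tree
        tau, lam = self.costs.transfer, self.costs.loss
        tol = 1e-9 * max(tree.root_age, 1.0)
        self.arcs: list[list[tuple[int, float, str]]] = [[] for _ in self.positions]

        def node_ends_slice(edge: str, i: int) -> bool:
            node = tree.nodes[edge]
            return (not node.is_leaf) and abs(node.age - sliced.boundaries[i + 1]) <= tol

        for k, (e, i) in enumerate(self.positions):
            if i == ROOT_SLICE:
                for child in tree.root.children:
                    self.arcs[k].append((self.index[(child.name, 0)], lam, "sl"))
                continue
            first, last = sliced.span[e]
            if i < last:  # plain descent within the same branch
                self.arcs[k].append((self.index[(e, i + 1)], 0.0, "descend"))
            elif node_ends_slice(e, i):  # speciation-loss through node e
                for child in tree.nodes[e].children:
                    self.arcs[k].append((self.index[(child.name, i + 1)], lam, "sl"))
            for f in sliced.alive[i]:  # transfer-loss jumps
                if f != e:
                    self.arcs[k].append((self.index[(f, i)], tau + lam, "tl"))
            self.arcs[k].sort(key=lambda a: a[0])

    def speciation_position(self, edge: str, i: int) -> bool:
        """True when position (edge, i) ends at an internal divergence."""
        if i == ROOT_SLICE:
            return True
        tree = self.sliced.tree
        node = tree.nodes[edge]
        tol = 1e-9 * max(tree.root_age, 1.0)
        return (not node.is_leaf) and abs(
            node.age - self.sliced.boundaries[i + 1]
        ) <= tol and self.sliced.span[edge][1] == i

    # -- shortest paths -------------------------------------------------------

    def _shortest_paths(self) -> None:
        P = len(self.positions)
        self.M = np.full((P, P), INF)
        self.pred = np.full((P, P), -1, dtype=np.int32)
        for s in range(P):
            dist = self.M[s]
            dist[s] = 0.0
            heap = [(0.0, s)]
            done = np.zeros(P, dtype=bool)
            while heap:
                d, u = heapq.heappop(heap)
                if done[u]:
                    continue
                done[u] = True
                for v, w, _ in self.arcs[u]:
                    nd = d + w
                    if nd < dist[v]:  # strict: first-found ties win (canonical)
                        dist[v] = nd
                        self.pred[s, v] = u
                        heapq.heappush(heap, (nd, v))

    def path(self, s: int, t: int) -> list[tuple[int, int]]:
        """Arc list (u, v) of the stored shortest path s → t."""
        if s == t:
            return []
        if not math.isfinite(self.M[s, t]):
            raise ReconciliationError("requested path between unconnected positions")
        arcs = []
        v = t
        while v != s:
            u = int(self.pred[s, v])
            arcs.append((u, v))
            v = u
        arcs.reverse()
        return arcs

    def terminal_index(self, species_leaf: str) -> int:
        return self.index[(species_leaf, self.sliced.n_slices - 1)]


# ---------------------------------------------------------------------------
# events and results


@dataclass
class EventRecord:
    """One explicit reconciliation event mapped onto the species tree."""

    event: str  # speciation | duplication | transfer | loss
    gene_node: str
    species_branch: str  # child-node name of the branch (node name for S)
    slice: int
    cost: float
    donor: str = ""
    recipient: str = ""


class ReconciliationResult:
    """Fitted reconciliation: optimal cost, events, mapping, diagnostics."""

    def __init__(
        self,
        model: "DTLReconciliation",
        total_cost: float,
        events: list[EventRecord],
        node_positions: dict[str, tuple[str, int, str]],
        leaf_mapping: dict[str, str],
    ):
        self.model = model
        self.total_cost = total_cost
        self.events = events
        self.node_positions = node_positions  # gene node -> (branch, slice, event)
        self.leaf_mapping = leaf_mapping

    @property
    def counts(self) -> dict[str, int]:
        out = {"speciation": 0, "duplication": 0, "transfer": 0, "loss": 0}
        for e in self.events:
            out[e.event] += 1
        return out

    def cost_from_events(self) -> float:
        """Recompute δ·#D + τ·#T + λ·#L from the event list."""
        c = self.model.costs
        n = self.counts
        return c.dup * n["duplication"] + c.transfer * n["transfer"] + c.loss * n["loss"]

    def transfers(self) -> list[EventRecord]:
        return [e for e in self.events if e.event == "transfer"]

    def to_event_table(self) -> pd.DataFrame:
        rows = [
            {
                "event": e.event,
                "gene_node": e.gene_node,
                "species_branch": e.species_branch,
                "slice": e.slice,
                "cost_component": e.cost,
                "donor": e.donor,
                "recipient": e.recipient,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "event",
                "gene_node",
                "species_branch",
                "slice",
                "cost_component",
                "donor",
                "recipient",
            ],
        )

    def date_events(self, mode: str = "branch", gene: str = "gene"):
        from .dating import date_events

        return date_events(self, self.model.species_tree, mode=mode, gene=gene)

    def to_recphyloxml(self) -> str:
        from .recphyloxml import to_recphyloxml

        return to_recphyloxml(self)

    def summary(self) -> str:
        n = self.counts
        c = self.model.costs
        lines = [
            "Dated DTL parsimony reconciliation",
            "==================================",
            f"gene leaves:        {len(self.leaf_mapping)}",
            f"costs (dup/transfer/loss): {c.dup:g}/{c.transfer:g}/{c.loss:g}",
            f"total cost:         {self.total_cost:g}",
            f"speciations:        {n['speciation']}",
            f"duplications:       {n['duplication']}",
            f"transfers:          {n['transfer']}",
            f"losses:             {n['loss']}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the model


class DTLReconciliation:
    """Parsimony DTL reconciliation model for one gene tree.

    Parameters
    ----------
    gene_tree : newick string or :class:`GeneTree`
    species_tree : :class:`DatedSpeciesTree`
    costs : :class:`CostScheme`, optional
    position_graph : prebuilt :class:`PositionGraph`, optional
        Pass a shared graph when reconciling many families against the same
        chronogram and cost scheme.
    """

    def __init__(
        self,
        gene_tree: Union[str, GeneTree],
        species_tree: DatedSpeciesTree,
        costs: Optional[CostScheme] = None,
        position_graph: Optional[PositionGraph] = None,
    ):
        self.gene_tree = as_gene_tree(gene_tree)
        self.species_tree = species_tree
        self.costs = costs or CostScheme()
        if position_graph is None:
            position_graph = PositionGraph(time_slice(species_tree), self.costs)
        elif position_graph.costs != self.costs:
            raise ValueError("position_graph built under different costs")
        self.graph = position_graph
        if not self.gene_tree.is_empty:
            self.gene_tree.map_to_species(species_tree)

    # -- fitting --------------------------------------------------------------

    def fit(self) -> ReconciliationResult:
        if self.gene_tree.is_empty:
            return ReconciliationResult(self, 0.0, [], {}, {})
        self._choice: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        g = self.graph
        M = g.M
        P = len(g.positions)
        delta, tau = self.costs.dup, self.costs.transfer

        # per-slice position indices for the transfer minimisation
        slice_members: dict[int, list[int]] = {}
        for k, (e, i) in enumerate(g.positions):
            slice_members.setdefault(i, []).append(k)

        C: dict[int, np.ndarray] = {}
        B: dict[int, np.ndarray] = {}
        Barg: dict[int, np.ndarray] = {}
        order = {id(n): k for k, n in enumerate(self.gene_tree.postorder)}

        for node in self.gene_tree.postorder:
            uid = id(node)
            if node.is_leaf:
                C[uid] = M[:, g.terminal_index(node.species)].copy()
                continue
            c1, c2 = node.children
            for c in (c1, c2):
                tot = M + C[id(c)][None, :]
                B[id(c)] = tot.min(axis=1)
                Barg[id(c)] = tot.argmin(axis=1)
            B1, B2 = B[id(c1)], B[id(c2)]

            dup_vec = delta + B1 + B2

            t_vec = np.full(P, INF)
            for i, members in slice_members.items():
                if i == ROOT_SLICE or len(members) < 2:
                    continue
                for child_stay, child_move in ((B1, B2), (B2, B1)):
                    vals = child_move[members]
                    k1 = int(np.argmin(vals))
                    m1 = vals[k1]
                    vals2 = vals.copy()
                    vals2[k1] = INF
                    m2 = vals2.min() if len(vals) > 1 else INF
                    for j, p in enumerate(members):
                        other = m2 if j == k1 else m1
                        cand = tau + child_stay[p] + other
                        if cand < t_vec[p]:
                            t_vec[p] = cand

            s_vec = np.full(P, INF)
            for k, (e, i) in enumerate(g.positions):
                if not g.speciation_position(e, i):
                    continue
                x = self.species_tree.nodes[e]
                f1, f2 = (c.name for c in x.children)
                q1, q2 = g.index[(f1, i + 1)], g.index[(f2, i + 1)]
                s_vec[k] = min(B1[q1] + B2[q2], B1[q2] + B2[q1])

            C[uid] = np.minimum(np.minimum(s_vec, dup_vec), t_vec)
            self._choice[uid] = (s_vec, dup_vec, t_vec)

        root = self.gene_tree.root
        croot = C[id(root)]
        p_star = int(np.argmin(croot))
        total = float(croot[p_star])
        if not math.isfinite(total):
            raise ReconciliationError("no feasible reconciliation found")

        events: list[EventRecord] = []
        node_positions: dict[str, tuple[str, int, str]] = {}
        leaf_mapping: dict[str, str] = {}
        self._backtrack(root, p_star, C, B, Barg, events, node_positions, leaf_mapping)
        result = ReconciliationResult(self, total, events, node_positions, leaf_mapping)
        assert abs(result.cost_from_events() - total) < 1e-6, "cost/count mismatch"
        return result

    # -- backtracking ---------------------------------------------------------

    def _emit_path(self, s: int, t: int, lineage: str, events: list[EventRecord]) -> None:
        g = self.graph
        lam, tau = self.costs.loss, self.costs.transfer
        for (u, v) in g.path(s, t):
            (eu, iu), (ev, iv) = g.positions[u], g.positions[v]
            if eu == ev:
                continue  # plain descent
            if iv == iu + 1 or iu == ROOT_SLICE:
                # speciation-loss through node eu: speciation + loss on sibling
                x = self.species_tree.nodes[eu]
                sibling = next(c.name for c in x.children if c.name != ev)
                events.append(EventRecord("speciation", lineage, eu, iv, 0.0))
                events.append(EventRecord("loss", lineage, sibling, iv, lam))
            else:
                # transfer-loss jump: transfer to ev plus loss of the donor copy
                events.append(
                    EventRecord(
                        "transfer", lineage, ev, iu, tau, donor=eu, recipient=ev
                    )
                )
                events.append(EventRecord("loss", lineage, eu, iu, lam))

    def _backtrack(self, node, p, C, B, Barg, events, node_positions, leaf_mapping):
        g = self.graph
        e, i = g.positions[p]
        if node.is_leaf:
            term = g.terminal_index(node.species)
            self._emit_path(p, term, node.label, events)
            leaf_mapping[node.label] = node.species
            node_positions[node.label] = (e, i, "C")
            return
        c1, c2 = node.children
        s_vec, d_vec, t_vec = self._choice[id(node)]
        s_val, d_val, t_val = s_vec[p], d_vec[p], t_vec[p]
        best = min(s_val, d_val, t_val)

        def place_child(child, start):
            q = int(Barg[id(child)][start])
            self._emit_path(start, q, child.label, events)
            self._backtrack(child, q, C, B, Barg, events, node_positions, leaf_mapping)

        if s_val == best:  # ties: speciation first
            x = self.species_tree.nodes[e]
            f1, f2 = (c.name for c in x.children)
            j = i + 1 if i != ROOT_SLICE else 0
            q1, q2 = g.index[(f1, j)], g.index[(f2, j)]
            B1, B2 = B[id(c1)], B[id(c2)]
            node_positions[node.label] = (e, i, "S")
            events.append(EventRecord("speciation", node.label, e, j, 0.0))
            if B1[q1] + B2[q2] <= B1[q2] + B2[q1]:
                place_child(c1, q1)
                place_child(c2, q2)
            else:
                place_child(c1, q2)
                place_child(c2, q1)
            return
        if d_val == best:
            node_positions[node.label] = (e, i, "D")
            events.append(
                EventRecord("duplication", node.label, e, i, self.costs.dup)
            )
            place_child(c1, p)
            place_child(c2, p)
            return
        # transfer: find the canonical achieving configuration
        B1, B2 = B[id(c1)], B[id(c2)]
        members = [k for k, (f, j) in enumerate(g.positions) if j == i]
        for stay_child, move_child, stayB, moveB in (
            (c1, c2, B1, B2),
            (c2, c1, B2, B1),
        ):
            for q in members:
                f, _ = g.positions[q]
                if f == e:
                    continue
                if abs(self.costs.transfer + stayB[p] + moveB[q] - t_val) <= 1e-9:
                    node_positions[node.label] = (e, i, "T")
                    events.append(
                        EventRecord(
                            "transfer",
                            node.label,
                            f,
                            i,
                            self.costs.transfer,
                            donor=e,
                            recipient=f,
                        )
                    )
                    place_child(stay_child, p)
                    place_child(move_child, q)
                    return
        raise AssertionError("transfer backtracking failed to find its argmin")


def reconcile(
    gene_tree: Union[str, GeneTree],
    species_tree: DatedSpeciesTree,
    costs: Optional[CostScheme] = None,
    position_graph: Optional[PositionGraph] = None,
) -> ReconciliationResult:
    """Fit one gene family; convenience wrapper over :class:`DTLReconciliation`."""
    return DTLReconciliation(gene_tree, species_tree, costs, position_graph).fit()


# ---------------------------------------------------------------------------
# aggregation over gene-tree sets (e.g. bootstrap replicates)


class AggregatedReconciliation:
    """Per-branch, per-event-type support across a set of gene trees."""

    def __init__(self, results: list[ReconciliationResult]):
        self.results = results
        self.best = results[0] if results else None

    def support_table(self) -> pd.DataFrame:
        """Fraction of trees with ≥1 event of each (branch, type), plus mean count."""
        keys: dict[tuple[str, str], list[int]] = {}
        for r in self.results:
            seen: dict[tuple[str, str], int] = {}
            for e in r.events:
                key = (e.species_branch, e.event)
                seen[key] = seen.get(key, 0) + 1
            for key, cnt in seen.items():
                keys.setdefault(key, []).append(cnt)
        n = len(self.results)
        rows = [
            {
                "species_branch": b,
                "event": ev,
                "support": len(cnts) / n,
                "mean_count": sum(cnts) / n,
            }
            for (b, ev), cnts in sorted(keys.items())
        ]
        return pd.DataFrame(
            rows, columns=["species_branch", "event", "support", "mean_count"]
        )

    def mean_counts(self) -> dict[str, float]:
        out = {"speciation": 0.0, "duplication": 0.0, "transfer": 0.0, "loss": 0.0}
        for r in self.results:
            for k, v in r.counts.items():
                out[k] += v
        return {k: v / len(self.results) for k, v in out.items()}


def reconcile_many(
    gene_trees: Sequence[Union[str, GeneTree]],
    species_tree: DatedSpeciesTree,
    costs: Optional[CostScheme] = None,
) -> AggregatedReconciliation:
    """Reconcile each tree of a set (e.g. bootstrap replicates) and aggregate."""
    costs = costs or CostScheme()
    graph = PositionGraph(time_slice(species_tree), costs)
    results = [
        DTLReconciliation(t, species_tree, costs, position_graph=graph).fit()
        for t in gene_trees
    ]
    return AggregatedReconciliation(results)


# ---------------------------------------------------------------------------
# independent brute-force oracle


def brute_force_min_cost(
    gene_tree: Union[str, GeneTree],
    species_tree: DatedSpeciesTree,
    costs: Optional[CostScheme] = None,
    cost_cap: float = 30.0,
    memoize: bool = True,
) -> float:
    """Minimum DTL cost by exhaustive recursion over atomic lineage moves.

    Independent of the dynamic program: epochs are re-derived directly from
    node ages and every history is assembled move by move (descend,
    speciation-loss, transfer-loss jump, or an S/D/T event) under a
    branch-and-bound budget.  Intended for ≤5 species and ≤5 gene leaves.
    Returns ``math.inf`` when no history costs ≤ ``cost_cap``.
    """
    costs = costs or CostScheme()
    gt = as_gene_tree(gene_tree)
    if gt.is_empty:
        return 0.0
    gt.map_to_species(species_tree)
    if costs.transfer + costs.loss <= 0:
        raise ValueError("brute force requires transfer + loss cost > 0")

    # independent epoch derivation: distinct internal ages, old -> young
    ages = sorted({n.age for n in species_tree.internal_nodes()}, reverse=True)
    bounds = ages + [0.0]
    n_epochs = len(bounds) - 1

    def alive(i: int) -> list[str]:
        lo, hi = bounds[i + 1], bounds[i]
        out = []
        for nd in species_tree.postorder():
            if nd.parent is None:
                continue
            if nd.parent.age >= hi - 1e-12 and nd.age <= lo + 1e-12:
                out.append(nd.name)
        return sorted(out)

    alive_sets = [alive(i) for i in range(n_epochs)]

    def ends_at(edge: str, i: int) -> bool:
        nd = species_tree.nodes[edge]
        return (not nd.is_leaf) and abs(nd.age - bounds[i + 1]) <= 1e-12

    HANDLE = -1  # zero-length pseudo-epoch above the species root
    # cache: (gene node, edge, epoch) -> (value, search budget). A finite
    # value is the exact minimum (branch-and-bound never discards cheaper
    # histories); INF only certifies infeasibility up to the stored budget.
    cache: dict[tuple[int, str, int], tuple[float, float]] = {}

    def bf(u, edge: str, i: int, budget: float) -> float:
        """Min cost to realise subtree u with its lineage entering (edge, i)."""
        if budget < -1e-12:
            return INF
        if not memoize:
            return _bf_inner(u, edge, i, budget)
        key = (id(u), edge, i)
        hit = cache.get(key)
        if hit is not None:
            val, bud = hit
            if val < INF:
                # val is the exact minimum; above the caller's budget it only
                # certifies infeasibility (returning it raw would let
                # over-budget costs masquerade as exhaustive minima)
                return val if val <= budget + 1e-12 else INF
            if budget <= bud + 1e-12:
                return INF
        best = _bf_inner(u, edge, i, budget)
        if hit is None or budget > hit[1] or best < INF:
            cache[key] = (best, budget)
        return best

    def _bf_inner(u, edge: str, i: int, budget: float) -> float:
        best = INF
        nd = species_tree.nodes[edge]
        at_handle = i == HANDLE
        at_divergence = at_handle or ends_at(edge, i)

        # no event in this epoch — pass through the bottom
        if at_divergence:
            for child in nd.children:  # speciation-loss into one daughter
                sub = bf(u, child.name, i + 1, budget - costs.loss)
                best = min(best, costs.loss + sub)
        elif nd.is_leaf and i == n_epochs - 1:
            if u.is_leaf and u.species == edge:
                best = 0.0
        else:
            best = min(best, bf(u, edge, i + 1, budget))

        # jump to a contemporaneous edge (transfer-loss); none at the handle
        if not at_handle:
            jump = costs.transfer + costs.loss
            for f in alive_sets[i]:
                if f != edge and jump <= budget + 1e-12:
                    best = min(best, jump + bf(u, f, i, min(budget, best) - jump))

        # an event here resolving an internal gene node
        if not u.is_leaf:
            u1, u2 = u.children
            # duplication: both children continue from this position
            rem = min(budget, best) - costs.dup
            if rem >= -1e-12:
                a = bf(u1, edge, i, rem)
                if a < INF:
                    b = bf(u2, edge, i, rem - a)
                    best = min(best, costs.dup + a + b)
            # transfer: one child stays, one starts on a contemporaneous edge
            if not at_handle:
                rem = min(budget, best) - costs.transfer
                if rem >= -1e-12:
                    for f in alive_sets[i]:
                        if f == edge:
                            continue
                        for stay, move in ((u1, u2), (u2, u1)):
                            a = bf(stay, edge, i, rem)
                            if a < INF:
                                b = bf(move, f, i, rem - a)
                                best = min(best, costs.transfer + a + b)
            # speciation at the bottom of this epoch
            if at_divergence:
                f1, f2 = (c.name for c in nd.children)
                for a_child, b_child in ((u1, u2), (u2, u1)):
                    a = bf(a_child, f1, i + 1, min(budget, best))
                    if a < INF:
                        b = bf(b_child, f2, i + 1, min(budget, best) - a)
                        best = min(best, a + b)
        return best

    best = INF
    root = gt.root
    # origination is free anywhere: the root handle or any (edge, epoch)
    best = min(best, bf(root, species_tree.root.name, HANDLE, cost_cap))
    for i in range(n_epochs):
        for e in alive_sets[i]:
            best = min(best, bf(root, e, i, min(best, cost_cap)))
    return best if best <= cost_cap + 1e-9 else INF
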