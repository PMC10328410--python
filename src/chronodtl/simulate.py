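"""Synthetic dated trees and gene families with known event histories.

The species tree is pure-birth (Yule) conditioned on a leaf count and
rescaled to a fixed root age (default 4.05 Ga, the approximate age of the
last universal common ancestor under an autocorrelated CIR relaxed clock).
Because there is no extinction, every lineage alive at any time survives to
the present, so "no transfers to the dead" holds by construction.

Gene families evolve forward in time down the species tree under a Gillespie
process: per-copy duplication, transfer and loss at constant rates (events
per lineage per Ga); at every species divergence each extant copy speciates
into both daughter lineages.  A transfer is additive — the donor copy
persists and a fresh copy starts on a uniformly chosen contemporaneous
recipient branch.  The observed gene tree is the genealogy of surviving
copies with lost lineages pruned and unifurcations suppressed; every event
is logged with its exact date, branches and visibility in the pruned tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .chronogram import DatedSpeciesTree, SpeciesNode

__all__ = [
    "SimulationConfig",
    "TrueEvent",
    "TrueEventLog",
    "GeneFamily",
    "simulate_species_chronogram",
    "simulate_gene_family",
    "yule_divergence_intervals",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Rates are events per gene lineage per Ga.  Defaults give the sparse,
    mostly recoverable regime used throughout the test fixtures.
    """

    n_species: int = 20
    root_age: float = 4.05
    birth_rate: float = 1.0
    r_dup: float = 0.05
    r_transfer: float = 0.10
    r_loss: float = 0.05
    origin: str = "root"
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not self.root_age > 0:
            raise ValueError("root_age must be positive")
        for r in (self.birth_rate, self.r_dup, self.r_transfer, self.r_loss):
            if r < 0:
                raise ValueError("rates must be nonnegative")


@dataclass
class TrueEvent:
    """One dated record of the generative history."""

    event: str  # speciation | duplication | transfer | loss
    time_ga: float
    donor_edge: str  # branch (child-node name) the acting copy sits on
    recipient_edge: str  # transfer target branch; "" otherwise
    copy_id: int
    survived: bool  # visible in the pruned observed gene tree


class TrueEventLog:
    """Ordered (old → young) list of :class:`TrueEvent` records."""

    def __init__(self, events: list[TrueEvent]):
        self.events = sorted(events, key=lambda e: (-e.time_ga, e.copy_id))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def count(self, event: str, survived_only: bool = False) -> int:
        return sum(
            1
            for e in self.events
            if e.event == event and (e.survived or not survived_only)
        )

    def parsimony_cost(self, dup: float, transfer: float, loss: float) -> float:
        """Price of the true history under a DTL cost scheme (speciation free)."""
        return (
            dup * self.count("duplication")
            + transfer * self.count("transfer")
            + loss * self.count("loss")
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.events])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def check_invariants(self, tree: DatedSpeciesTree) -> None:
        """Raise AssertionError unless every record is temporally consistent."""
        for e in self.events:
            young, old = tree.branch_interval(e.donor_edge)
            if e.event == "speciation":
                node = tree.nodes[e.donor_edge]
                assert not node.is_leaf and abs(e.time_ga - node.age) < 1e-9
            else:
                assert young < e.time_ga < old, (e, young, old)
            if e.event == "transfer":
                assert e.recipient_edge and e.recipient_edge != e.donor_edge
                ry, ro = tree.branch_interval(e.recipient_edge)
                assert ry < e.time_ga < ro, "recipient not alive at transfer time"


@dataclass
class GeneFamily:
    """Simulated gene family: observed tree, truth log and bookkeeping."""

    newick: Optional[str]  # None when every copy was lost
    log: TrueEventLog
    extinct: bool
    n_leaves: int
    total_lineage_time: float  # summed alive-time of all copies, Ga
    leaf_species: dict[str, str] = field(default_factory=dict)


def yule_divergence_intervals(
    n_species: int, birth_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Waiting times between successive divergences of a pure-birth tree.

    Entry ``j`` is the Exp(k·b)-distributed interval while ``k = j + 2``
    lineages exist (the interval after the root split and, last, the hanging
    time after the ``n``-th lineage appears).  This is the order-statistic
    structure a Yule tree's node ages are built from.
    """
    ks = np.arange(2, n_species + 1)
    return rng.exponential(1.0 / (ks * birth_rate))


def simulate_species_chronogram(config: SimulationConfig) -> DatedSpeciesTree:
    """Pure-birth species tree on ``n_species`` leaves rescaled to ``root_age``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    intervals = yule_divergence_intervals(n, config.birth_rate, rng)

    # forward construction: split times measured from the root divergence;
    # the j-th split (j=0 is the root) happens after j accumulated intervals
    root = SpeciesNode(name="")
    active: list[SpeciesNode] = [root]
    split_times = np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    for st in split_times:
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node._split_time = float(st)  # type: ignore[attr-defined]
        c1, c2 = SpeciesNode(name=""), SpeciesNode(name="")
        node.children = [c1, c2]
        active.extend([c1, c2])
    present = float(intervals.sum())  # final hanging interval included

    # ages: present minus split time, rescaled so the root sits at root_age
    scale = config.root_age / present
    leaf_counter = 1

    # deterministic leaf naming: depth-first in creation order
    def walk(node: SpeciesNode) -> None:
        nonlocal leaf_counter
        if node.children:
            node.age = (present - node._split_time) * scale  # type: ignore[attr-defined]
            for c in node.children:
                walk(c)
        else:
            node.age = 0.0
            node.name = f"s{leaf_counter:02d}"
            leaf_counter += 1

    walk(root)
    return DatedSpeciesTree(root)


class _Copy:
    """Genealogy node of the gene-copy forest (internal helper)."""

    __slots__ = ("time", "label", "children")

    def __init__(self, time: float, label: str = "", children=None):
        self.time = time
        self.label = label
        self.children = children or []


def simulate_gene_family(
    tree: DatedSpeciesTree,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> GeneFamily:
    """Evolve one gene family down *tree* under the Gillespie DTL process.

    The family originates as a single copy at the species root and every
    event is logged.  Returns an extinct-flagged family with ``newick=None``
    when no copy survives to the present.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    events: list[TrueEvent] = []
    copy_counter = [0]
    species_copy_counter: dict[str, int] = {}
    exposure = [0.0]
    rates = np.array([config.r_dup, config.r_transfer, config.r_loss])
    total_rate = float(rates.sum())

    def alive_edges(age: float) -> list[str]:
        out = []
        for node in tree.postorder():
            if node.parent is None:
                continue
            if node.age < age < node.parent.age:
                out.append(node.name)
        return sorted(out)

    def new_copy_id() -> int:
        copy_counter[0] += 1
        return copy_counter[0]

    def descend(edge: str, t_start: float, copy_id: int) -> Optional[_Copy]:
        """Simulate one copy on *edge* from age t_start toward the present."""
        node = tree.nodes[edge]
        t = t_start
        while True:
            dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            if t - dt <= node.age:
                exposure[0] += t - node.age
                break
            t -= dt
            exposure[0] += dt
            kind = ["duplication", "transfer", "loss"][
                int(rng.choice(3, p=rates / total_rate))
            ]
            if kind == "loss":
                events.append(TrueEvent("loss", t, edge, "", copy_id, False))
                return None
            if kind == "duplication":
                ev = TrueEvent("duplication", t, edge, "", copy_id, False)
                events.append(ev)
                left = descend(edge, t, copy_id)
                right = descend(edge, t, new_copy_id())
                ev.survived = left is not None and right is not None
                if left and right:
                    return _Copy(t, children=[left, right])
                return left or right
            # transfer
            candidates = [e for e in alive_edges(t) if e != edge]
            if not candidates:
                continue  # nowhere to go; the clock still ticked
            recipient = candidates[int(rng.integers(len(candidates)))]
            ev = TrueEvent("transfer", t, edge, recipient, copy_id, False)
            events.append(ev)
            moved = descend(recipient, t, new_copy_id())
            ev.survived = moved is not None
            stayed = descend(edge, t, copy_id)
            if moved and stayed:
                return _Copy(t, children=[stayed, moved])
            return moved or stayed

        if node.is_leaf:
            k = species_copy_counter.get(node.name, 0) + 1
            species_copy_counter[node.name] = k
            return _Copy(0.0, label=f"{node.name}|copy{k}")
        ev = TrueEvent("speciation", node.age, node.name, "", copy_id, False)
        events.append(ev)
        left = descend(node.children[0].name, node.age, copy_id)
        right = descend(node.children[1].name, node.age, new_copy_id())
        ev.survived = left is not None and right is not None
        if left and right:
            return _Copy(node.age, children=[left, right])
        return left or right

    # origin: a single copy at the root divergence, which speciates at once
    root_id = new_copy_id()
    root_ev = TrueEvent("speciation", tree.root.age, tree.root.name, "", root_id, False)
    events.append(root_ev)
    left = descend(tree.root.children[0].name, tree.root.age, root_id)
    right = descend(tree.root.children[1].name, tree.root.age, new_copy_id())
    root_ev.survived = left is not None and right is not None
    if left and right:
        genealogy: Optional[_Copy] = _Copy(tree.root.age, children=[left, right])
    else:
        genealogy = left or right

    log = TrueEventLog(events)
    if genealogy is None:
        return GeneFamily(None, log, True, 0, exposure[0])

    leaf_species: dict[str, str] = {}

    def to_newick(c: _Copy, parent_time: float) -> str:
        bl = parent_time - c.time
        if not c.children:
            leaf_species[c.label] = c.label.split("|", 1)[0]
            return f"{c.label}:{bl:.10g}"
        inner = ",".join(
            to_newick(ch, c.time)
            for ch in sorted(c.children, key=_min_leaf_label)
        )
        return f"({inner}):{bl:.10g}"

    if not genealogy.children:
        newick = to_newick(genealogy, tree.root.age).rsplit(":", 1)[0] + ";"
    else:
        newick = (
            "("
            + ",".join(
                to_newick(ch, genealogy.time)
                for ch in sorted(genealogy.children, key=_min_leaf_label)
            )
            + ");"
        )
    return GeneFamily(
        newick, log, False, len(leaf_species), exposure[0], leaf_species
    )


def _min_leaf_label(c: _Copy) -> str:
    while c.children:
        c = min(c.children, key=_min_leaf_label)
    return c.label
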