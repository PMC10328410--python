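"""Assign time ranges and midpoint dates to reconciliation events.

A reconciliation localises each event to a species branch; within that
branch the event could have happened anywhere, so a duplication, transfer
or loss is reported as the interval between the branch's two node dates
(down to 0 for leaf branches) with its midpoint as the point summary.
Speciations sit at nodes and get a degenerate interval.  Node dates are the
midpoints of 95% credibility intervals when the chronogram carries them,
point ages otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import pandas as pd

from .chronogram import DatedSpeciesTree
from .reconcile import ReconciliationResult, ReconciliationError

__all__ = ["DatedEvent", "date_events", "earliest_event", "round_ga", "events_table"]

# tie-break priority among event types (higher wins)
_TYPE_RANK = {"speciation": 3, "duplication": 2, "transfer": 1, "loss": 0}


def round_ga(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for reported dates."""
    scale = 10**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass
class DatedEvent:
    """A reconciliation event with its temporal bounds in Ga."""

    gene: str
    event: str  # speciation | duplication | transfer | loss
    branch: str
    t_old: float
    t_young: float
    midpoint: float
    leaf_branch: bool

    def range_str(self, ndigits: int = 2) -> str:
        """Printed form: a single date for point events, else ``young–old``."""
        if self.t_old == self.t_young:
            return f"{round_ga(self.t_old, ndigits):.{ndigits}f}"
        return (
            f"{round_ga(self.t_young, ndigits):.{ndigits}f}"
            f"–{round_ga(self.t_old, ndigits):.{ndigits}f}"
        )


def date_events(
    rec: ReconciliationResult,
    tree: DatedSpeciesTree,
    mode: str = "branch",
    gene: str = "gene",
) -> list[DatedEvent]:
    """Date every event of a reconciliation on its species branch.

    ``mode="branch"`` (default) spans the full branch — parent node date to
    child node date, leaf branches extending to the present.  ``mode="slice"``
    additionally intersects the range with the event's time slice, which the
    dated reconciliation localises more tightly; slice mode works on point
    ages throughout so intersections stay well formed.

    Transfers are dated on their recipient branch.  The mapping is one
    DatedEvent per reconciliation event, in the same order.
    """
    if mode not in ("branch", "slice"):
        raise ValueError(f"unknown dating mode {mode!r}")
    use_dates = mode == "branch"
    boundaries = rec.model.graph.sliced.boundaries if mode == "slice" else None
    out: list[DatedEvent] = []
    for ev in rec.events:
        branch = ev.species_branch
        if branch not in tree.nodes:
            raise ReconciliationError(
                f"event references branch {branch!r} absent from the chronogram"
            )
        node = tree.nodes[branch]
        if ev.event == "speciation":
            d = node.date if use_dates else node.age
            out.append(DatedEvent(gene, ev.event, branch, d, d, d, False))
            continue
        t_young, t_old = tree.branch_interval(branch, use_dates=use_dates)
        if mode == "slice" and 0 <= ev.slice < len(boundaries) - 1:
            lo, hi = boundaries[ev.slice + 1], boundaries[ev.slice]
            t_young, t_old = max(t_young, lo), min(t_old, hi)
        mid = 0.5 * (t_old + t_young)
        out.append(
            DatedEvent(gene, ev.event, branch, t_old, t_young, mid, node.is_leaf)
        )
    return out


def earliest_event(events: Sequence[DatedEvent]) -> Optional[DatedEvent]:
    """The chronologically earliest event: maximum midpoint date.

    Ties go to the larger ``t_old``, then by event-type priority
    speciation > duplication > transfer > loss, then by branch name.
    Returns ``None`` for an empty list.
    """
    if not events:
        return None
    return max(
        events,
        key=lambda e: (e.midpoint, e.t_old, _TYPE_RANK[e.event], e.branch),
    )


def events_table(events: Iterable[DatedEvent]) -> pd.DataFrame:
    """Long-form TSV-ready table of dated events."""
    return pd.DataFrame(
        [asdict(e) for e in events],
        columns=["gene", "event", "branch", "t_old", "t_young", "midpoint", "leaf_branch"],
    )
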