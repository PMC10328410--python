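"""Temporal trend summaries over dated gene events.

Per-gene event-count tables (losses, duplications, transfers, speciations
and their sum), histograms of event midpoints in fixed-width time bins
(proportions of each gene's total events per bin), and chronological gene
ordering by the midpoint of each gene's earliest event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dating import DatedEvent, earliest_event

__all__ = ["TrendTable", "summarize_counts", "bin_midpoints", "order_genes"]

EVENT_TYPES = ("loss", "duplication", "transfer", "speciation")


@dataclass
class TrendTable:
    """Binned midpoint histogram plus per-gene totals.

    ``counts`` is long-form (gene, event, bin_low, bin_high, count,
    proportion) where proportions are of the gene's total events across all
    types and bins, so they sum to 1 for every gene with at least one event.
    """

    bin_width: float
    bin_edges: np.ndarray  # ascending from 0
    counts: pd.DataFrame
    totals: pd.DataFrame  # per-gene per-type counts and total

    def gene_proportions(self, gene: str) -> pd.DataFrame:
        return self.counts[self.counts["gene"] == gene].reset_index(drop=True)


def summarize_counts(
    events_by_gene: Mapping[str, Sequence[DatedEvent]]
) -> pd.DataFrame:
    """Per-gene counts by event type; total = loss + dup + transfer + speciation."""
    rows = []
    for gene in sorted(events_by_gene):
        events = events_by_gene[gene]
        row = {"gene": gene}
        for t in EVENT_TYPES:
            row[t] = sum(1 for e in events if e.event == t)
        row["total"] = sum(row[t] for t in EVENT_TYPES)
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", *EVENT_TYPES, "total"])


def bin_midpoints(
    events_by_gene: Mapping[str, Sequence[DatedEvent]],
    bin_width: float = 0.25,
    max_age: Optional[float] = None,
) -> TrendTable:
    """Histogram event midpoints per gene and type.

    Bins are half-open ``[low, high)`` ascending from 0; the oldest bin is
    closed so a midpoint exactly at the top edge is still counted.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    all_mid = [e.midpoint for evs in events_by_gene.values() for e in evs]
    top = max_age if max_age is not None else (max(all_mid) if all_mid else bin_width)
    n_bins = max(1, int(np.ceil(top / bin_width - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width

    rows = []
    for gene in sorted(events_by_gene):
        events = events_by_gene[gene]
        total = len(events)
        grid = {
            (t, b): 0 for t in EVENT_TYPES for b in range(n_bins)
        }
        for e in events:
            b = int(e.midpoint // bin_width)
            if b >= n_bins:  # closed top bin
                b = n_bins - 1
            grid[(e.event, b)] += 1
        for t in EVENT_TYPES:
            for b in range(n_bins):
                c = grid[(t, b)]
                if c == 0:
                    continue
                rows.append(
                    {
                        "gene": gene,
                        "event": t,
                        "bin_low": edges[b],
                        "bin_high": edges[b + 1],
                        "count": c,
                        "proportion": c / total if total else 0.0,
                    }
                )
    counts = pd.DataFrame(
        rows, columns=["gene", "event", "bin_low", "bin_high", "count", "proportion"]
    )
    return TrendTable(
        bin_width=bin_width,
        bin_edges=edges,
        counts=counts,
        totals=summarize_counts(events_by_gene),
    )


def order_genes(
    earliest_midpoints: Mapping[str, float] | Mapping[str, Sequence[DatedEvent]]
) -> list[str]:
    """Genes in chronological order of their earliest-event midpoint.

    Accepts either ``gene -> midpoint`` or ``gene -> dated events`` (the
    earliest event is extracted).  Oldest first; ties alphabetical.
    """
    mids: dict[str, float] = {}
    for gene, val in earliest_midpoints.items():
        if isinstance(val, (int, float)):
            mids[gene] = float(val)
        else:
            ev = earliest_event(val)
            if ev is None:
                raise ValueError(f"gene {gene!r} has no events to order by")
            mids[gene] = ev.midpoint
    return sorted(mids, key=lambda g: (-mids[g], g))


def plot_timeline(events_by_gene, ax=None, seed: int = 0):
    """Dot timeline of event midpoints per gene (oldest genes on top)."""
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(seed)
    order = order_genes(events_by_gene)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.5 * len(order) + 1))
    colors = {
        "speciation": "tab:blue",
        "loss": "tab:red",
        "duplication": "tab:green",
        "transfer": "tab:orange",
    }
    for y, gene in enumerate(reversed(order)):
        for e in events_by_gene[gene]:
            ax.scatter(
                e.midpoint,
                y + rng.uniform(-0.2, 0.2),
                s=12,
                color=colors[e.event],
                alpha=0.7,
            )
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(list(reversed(order)))
    ax.set_xlabel("Ga before present")
    ax.invert_xaxis()
    return ax
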