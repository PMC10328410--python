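"""Dated species chronograms: parsing, validation, and time slicing.

A chronogram is a rooted, binary, ultrametric phylogeny whose node ages are
measured in Ga (billions of years) before present; leaves sit at age 0 and
time increases into the past.  All temporal conventions of the package live
here.  Internal nodes may carry 95% credibility intervals on their age,
written in newick as a bracketed node comment ``[&ci={low,high}]``; when an
interval is present the node's *working date* is its midpoint, otherwise the
point age is used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

__all__ = [
    "ChronogramError",
    "SpeciesNode",
    "DatedSpeciesTree",
    "TimeSlicedTree",
    "parse_chronogram",
    "time_slice",
]

#: relative (to root age) tolerance for ultrametricity of input branch lengths
ULTRAMETRIC_RTOL = 1e-6

_CI_RE = re.compile(r"&?ci=\{([^,}]+),([^,}]+)\}")


class ChronogramError(ValueError):
    """Raised for chronograms violating the dated-tree contract."""


@dataclass
class SpeciesNode:
    """A node of a :class:`DatedSpeciesTree`.

    Every non-root node also names the *branch* (edge) above it, so branch
    identifiers in event tables are simply child-node names.
    """

    name: str
    age: float = 0.0
    ci: Optional[tuple[float, float]] = None
    parent: Optional["SpeciesNode"] = None
    children: list["SpeciesNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def date(self) -> float:
        """Working date: CI midpoint when an interval is present, else age."""
        if self.ci is not None:
            return 0.5 * (self.ci[0] + self.ci[1])
        return self.age

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SpeciesNode({self.name!r}, age={self.age:.4g})"


class DatedSpeciesTree:
    """Rooted binary ultrametric species tree with node ages in Ga.

    Parameters
    ----------
    root:
        Root :class:`SpeciesNode` of a fully linked node structure.  Children
    are canonically ordered (by smallest descendant leaf label) and node
    names are assigned to unnamed internal nodes at construction.
    """

    def __init__(self, root: SpeciesNode):
        self.root = root
        self._canonicalize()
        self._index()
        self.validate()

    # -- construction helpers -------------------------------------------------

    def _canonicalize(self) -> None:
        def min_leaf(node: SpeciesNode) -> str:
            while node.children:
                node = min(node.children, key=min_leaf_key)
            return node.name

        def min_leaf_key(node: SpeciesNode) -> str:
            return min_leaf(node)

        def rec(node: SpeciesNode) -> None:
            for c in node.children:
                c.parent = node
                rec(c)
            node.children.sort(key=min_leaf_key)

        rec(self.root)
        self.root.parent = None

    def _index(self) -> None:
        # deterministic post-order; unnamed internal nodes get n1, n2, ...
        self._postorder: list[SpeciesNode] = []

        def rec(node: SpeciesNode) -> None:
            for c in node.children:
                rec(c)
            self._postorder.append(node)

        rec(self.root)
        counter = 1
        seen: set[str] = {n.name for n in self._postorder if n.name}
        for node in self._postorder:
            if not node.name:
                while f"n{counter}" in seen:
                    counter += 1
                node.name = f"n{counter}"
                seen.add(node.name)
        self.nodes: dict[str, SpeciesNode] = {}
        for node in self._postorder:
            if node.name in self.nodes:
                raise ChronogramError(f"duplicate node label {node.name!r}")
            self.nodes[node.name] = node
        self.leaves: dict[str, SpeciesNode] = {
            n.name: n for n in self._postorder if n.is_leaf
        }

    # -- basic queries --------------------------------------------------------

    @property
    def root_age(self) -> float:
        return self.root.age

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def postorder(self) -> Iterator[SpeciesNode]:
        return iter(self._postorder)

    def internal_nodes(self) -> list[SpeciesNode]:
        return [n for n in self._postorder if not n.is_leaf]

    def branch_interval(self, branch: str, use_dates: bool = False) -> tuple[float, float]:
        """(young, old) endpoints in Ga of the branch above node *branch*.

        With ``use_dates=True`` endpoints are CI-midpoint working dates.
        The root's zero-length handle returns a degenerate interval.
        """
        node = self.nodes[branch]
        get = (lambda n: n.date) if use_dates else (lambda n: n.age)
        if node.parent is None:
            return (get(node), get(node))
        return (get(node), get(node.parent))

    def validate(self) -> None:
        if self.n_leaves < 2:
            raise ChronogramError("a dated species tree needs at least 2 leaves")
        for node in self._postorder:
            if node.children and len(node.children) != 2:
                raise ChronogramError(
                    f"polytomy at node {node.name!r}: trees must be binary"
                )
            if node.is_leaf and abs(node.age) > 1e-9 * max(1.0, self.root_age):
                raise ChronogramError(f"leaf {node.name!r} has nonzero age {node.age}")
            if node.parent is not None and not node.parent.age > node.age:
                raise ChronogramError(
                    f"parent {node.parent.name!r} (age {node.parent.age}) is not "
                    f"older than child {node.name!r} (age {node.age})"
                )
            if node.ci is not None:
                lo, hi = node.ci
                if not (lo <= node.age <= hi):
                    raise ChronogramError(
                        f"node {node.name!r}: age {node.age} outside CI [{lo}, {hi}]"
                    )
        if not self.root.age > 0:
            raise ChronogramError("root age must be positive")

    # -- newick I/O -----------------------------------------------------------

    def to_newick(self, include_ci: bool = True) -> str:
        """Serialize with branch lengths in Ga; CIs as ``[&ci={low,high}]``."""

        def rec(node: SpeciesNode) -> str:
            if node.children:
                inner = ",".join(rec(c) for c in node.children)
                label = f"({inner}){node.name}"
            else:
                label = node.name
            if node.ci is not None and include_ci:
                label += f"[&ci={{{node.ci[0]:.10g},{node.ci[1]:.10g}}}]"
            if node.parent is not None:
                label += f":{node.parent.age - node.age:.10g}"
            return label

        return rec(self.root) + ";"

    @classmethod
    def from_newick(
        cls, newick_text: str, age_mode: str = "branch-lengths"
    ) -> "DatedSpeciesTree":
        return parse_chronogram(newick_text, age_mode=age_mode)


def _extract_ci(dnode: dendropy.Node) -> Optional[tuple[float, float]]:
    for comment in dnode.comments or []:
        m = _CI_RE.search(comment)
        if m:
            lo, hi = float(m.group(1)), float(m.group(2))
            if hi < lo:
                lo, hi = hi, lo
            return (lo, hi)
    return None


def parse_chronogram(newick_text: str, age_mode: str = "branch-lengths") -> DatedSpeciesTree:
    """Parse a newick chronogram into a :class:`DatedSpeciesTree`.

    ``age_mode="branch-lengths"`` reads branch lengths as durations in Ga and
    requires the tree to be ultrametric within a relative tolerance of
    ``1e-6`` of the root age; ages are then re-projected to exact
    ultrametricity by averaging root-to-leaf depths.  ``age_mode="node-labels"``
    reads internal node labels directly as ages in Ga (leaves at 0).
    """
    if age_mode not in ("branch-lengths", "node-labels"):
        raise ValueError(f"unknown age_mode {age_mode!r}")
    dtree = dendropy.Tree.get(
        data=newick_text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
        extract_comment_metadata=False,
    )

    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    dup = {l for l in labels if labels.count(l) > 1}
    if dup:
        raise ChronogramError(f"duplicate leaf labels: {sorted(dup)}")

    def build(dnode: dendropy.Node) -> SpeciesNode:
        if dnode.is_leaf():
            name = dnode.taxon.label
        else:
            name = dnode.label or ""
        node = SpeciesNode(name=name, ci=_extract_ci(dnode))
        node.children = [build(c) for c in dnode.child_nodes()]
        return node

    root = build(dtree.seed_node)

    if age_mode == "node-labels":
        def assign(node: SpeciesNode, dnode: dendropy.Node) -> None:
            if node.children:
                try:
                    node.age = float(dnode.label)
                except (TypeError, ValueError):
                    raise ChronogramError(
                        f"internal node lacks a numeric age label: {dnode.label!r}"
                    ) from None
            else:
                node.age = 0.0
            for c, dc in zip(node.children, dnode.child_nodes()):
                assign(c, dc)

        assign(root, dtree.seed_node)
        return DatedSpeciesTree(root)

    # branch-lengths mode: depths from root, ultrametricity check, re-projection
    depths: dict[int, float] = {}

    def depth(node: SpeciesNode, dnode: dendropy.Node, d: float) -> None:
        depths[id(node)] = d
        for c, dc in zip(node.children, dnode.child_nodes()):
            bl = dc.edge.length
            if bl is None:
                raise ChronogramError("missing branch length in newick input")
            depth(c, dc, d + bl)

    def iter_nodes(node: SpeciesNode):
        yield node
        for c in node.children:
            yield from iter_nodes(c)

    depth(root, dtree.seed_node, 0.0)
    leaf_nodes = [n for n in iter_nodes(root) if n.is_leaf]
    leaf_depths = sorted(depths[id(n)] for n in leaf_nodes)
    median_depth = leaf_depths[len(leaf_depths) // 2]
    tol = ULTRAMETRIC_RTOL * max(median_depth, 1e-300)
    worst = max(leaf_nodes, key=lambda n: abs(depths[id(n)] - median_depth))
    if abs(depths[id(worst)] - median_depth) > tol:
        raise ChronogramError(
            f"tree is not ultrametric: leaf {worst.name!r} at depth "
            f"{depths[id(worst)]:.9g} vs typical root-to-leaf depth "
            f"{median_depth:.9g}"
        )

    # exact re-projection: a node's age = mean path length to its leaves
    def project(node: SpeciesNode) -> tuple[float, int]:
        if node.is_leaf:
            node.age = 0.0
            return 0.0, 1
        tot, cnt = 0.0, 0
        for c in node.children:
            bl = depths[id(c)] - depths[id(node)]
            s, k = project(c)
            tot += s + bl * k
            cnt += k
        node.age = tot / cnt
        return tot, cnt

    project(root)
    return DatedSpeciesTree(root)


@dataclass
class TimeSlicedTree:
    """Decomposition of a chronogram into inter-divergence time slices.

    ``boundaries`` are the distinct internal-node ages in decreasing order
    followed by 0; slice *i* is the open interval ``(boundaries[i+1],
    boundaries[i])`` and ``alive[i]`` lists the branches (child-node names)
    spanning it.  Equal node ages are merged into a single boundary.
    """

    tree: DatedSpeciesTree
    boundaries: list[float]
    alive: list[tuple[str, ...]]
    span: dict[str, tuple[int, int]]  # branch -> (first slice, last slice)

    @property
    def n_slices(self) -> int:
        return len(self.alive)

    def slice_interval(self, i: int) -> tuple[float, float]:
        """(young, old) endpoints of slice i."""
        return (self.boundaries[i + 1], self.boundaries[i])

    def slice_of_age(self, age: float) -> int:
        """Index of the slice whose open interval contains *age*."""
        for i in range(self.n_slices):
            young, old = self.slice_interval(i)
            if young < age < old:
                return i
        raise ValueError(f"age {age} coincides with a boundary or is out of range")


def time_slice(tree: DatedSpeciesTree, atol: float = 1e-12) -> TimeSlicedTree:
    """Slice a chronogram at its distinct internal-node ages.

    Node ages closer than *atol* (relative to root age) are merged into one
    boundary, so simultaneous divergences share a slice boundary instead of
    creating an empty sliver.
    """
    tol = atol * max(tree.root_age, 1.0)
    ages = sorted({n.age for n in tree.internal_nodes()}, reverse=True)
    boundaries: list[float] = []
    for a in ages:
        if not boundaries or boundaries[-1] - a > tol:
            boundaries.append(a)
    boundaries.append(0.0)

    def boundary_index(age: float) -> int:
        for i, b in enumerate(boundaries):
            if abs(b - age) <= tol:
                return i
        raise AssertionError("node age not on a boundary")

    n_slices = len(boundaries) - 1
    alive_sets: list[list[str]] = [[] for _ in range(n_slices)]
    span: dict[str, tuple[int, int]] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        top = boundary_index(node.parent.age)
        bot = boundary_index(node.age) if not node.is_leaf else n_slices
        # edge spans slices top .. bot-1
        first, last = top, bot - 1
        span[node.name] = (first, last)
        for i in range(first, last + 1):
            alive_sets[i].append(node.name)
    alive = [tuple(sorted(s)) for s in alive_sets]
    for i, s in enumerate(alive):
        if not s:
            raise ChronogramError(f"empty time slice {i}")
    return TimeSlicedTree(tree=tree, boundaries=boundaries, alive=alive, span=span)
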