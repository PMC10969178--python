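"""Weighted directed graphs with exact rational arc weights.

The graph is the carrier of the cross-weight function

    w(B, C) = sum of a_ij over ordered pairs i in B, j in C,

which everything downstream (characteristic functions, envelopes,
augmented flow networks) is built from.  Node identifiers are opaque
strings; a dense index is assigned in first-seen order and used for all
internal set encodings.  Weights are stored as :class:`fractions.Fraction`
so that every derived quantity (g-values, envelope breakpoints, community
strengths) can be computed exactly; every Python float is a rational, so
no input is excluded by this choice.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Mapping

import networkx as nx

__all__ = ["WeightedDigraph", "read_edgelist_tsv", "read_graphml", "as_fraction"]


def as_fraction(x) -> Fraction:
    """Convert a weight to an exact Fraction (floats convert exactly)."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(x)  # accepts "3", "1/2", "0.25"
    raise TypeError(f"cannot interpret weight of type {type(x).__name__}")


class WeightedDigraph:
    """Finite node set with nonnegative weighted arcs.

    Parallel arcs are merged by summing weights at insertion time.
    Self-loops are allowed; their weight counts in w(B, B) when the node
    is in B.
    """

    def __init__(self, nodes: Iterable[str] = (), arcs: Mapping | None = None):
        self._nodes: list[str] = []
        self._index: dict[str, int] = {}
        self._w: dict[tuple[str, str], Fraction] = {}
        for v in nodes:
            self.add_node(v)
        if arcs:
            for (i, j), a in arcs.items():
                self.add_arc(i, j, a)

    # -- construction -------------------------------------------------

    def add_node(self, v) -> None:
        v = str(v)
        if v not in self._index:
            self._index[v] = len(self._nodes)
            self._nodes.append(v)

    def add_arc(self, i, j, weight=1) -> None:
        w = as_fraction(weight)
        if w < 0:
            raise ValueError(f"negative arc weight {weight!r} on ({i}, {j})")
        i, j = str(i), str(j)
        self.add_node(i)
        self.add_node(j)
        self._w[(i, j)] = self._w.get((i, j), Fraction(0)) + w

    def add_edge(self, i, j, weight=1) -> None:
        """Undirected edge: one arc in each direction, each of the full weight."""
        self.add_arc(i, j, weight)
        self.add_arc(j, i, weight)

    # -- basic queries -------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def node_set(self) -> frozenset:
        return frozenset(self._nodes)

    @property
    def arcs(self) -> dict[tuple[str, str], Fraction]:
        return dict(self._w)

    def index(self, v: str) -> int:
        """Dense first-seen index of a node (used for set encodings)."""
        try:
            return self._index[v]
        except KeyError:
            raise KeyError(f"unknown node identifier: {v!r}") from None

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, v) -> bool:
        return str(v) in self._index

    def _check_nodes(self, S: Iterable[str]) -> frozenset:
        S = frozenset(str(v) for v in S)
        for v in S:
            if v not in self._index:
                raise KeyError(f"unknown node identifier: {v!r}")
        return S

    # -- cross weight --------------------------------------------------

    def w(self, B: Iterable[str], C: Iterable[str]) -> Fraction:
        """Cross weight w(B, C) = sum of a_ij over i in B, j in C."""
        B = self._check_nodes(B)
        C = self._check_nodes(C)
        if not B or not C:
            return Fraction(0)
        total = Fraction(0)
        for (i, j), a in self._w.items():
            if i in B and j in C:
                total += a
        return total

    def in_weight(self, B: Iterable[str], j) -> Fraction:
        """w(B, {j}): total weight of arcs from B into node j."""
        return self.w(B, [j])

    def total_weight(self) -> Fraction:
        return sum(self._w.values(), Fraction(0))

    # -- serialization -------------------------------------------------

    def to_tsv(self) -> str:
        lines = ["source\ttarget\tweight"]
        for (i, j), a in sorted(self._w.items()):
            lines.append(f"{i}\t{j}\t{a}")
        touched = {v for arc in self._w for v in arc}
        for v in self._nodes:  # isolated nodes: single-column declaration
            if v not in touched:
                lines.append(v)
        return "\n".join(lines) + "\n"

    def __repr__(self) -> str:
        return f"WeightedDigraph(|V|={len(self)}, |A|={len(self._w)})"


class GraphFormatError(ValueError):
    """Raised on malformed graph input; carries a line number when known."""


def read_edgelist_tsv(source, undirected: bool = False) -> WeightedDigraph:
    """Load a tab-separated edge list: ``source<TAB>target[<TAB>weight]``.

    Lines starting with ``#`` are comments; a header line whose weight
    column is non-numeric is skipped.  With ``undirected=True`` every
    edge is expanded into two arcs of the stated weight.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    g = WeightedDigraph()
    seen_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 1:  # isolated-node declaration
            g.add_node(parts[0])
            seen_data = True
            continue
        if len(parts) not in (2, 3):
            raise GraphFormatError(
                f"line {lineno}: expected 1-3 columns, got {len(parts)}"
            )
        weight = parts[2] if len(parts) == 3 else "1"
        try:
            w = as_fraction(weight)
        except (ValueError, ZeroDivisionError):
            if not seen_data:  # tolerated header on the first data line
                continue
            raise GraphFormatError(f"line {lineno}: bad weight {weight!r}") from None
        seen_data = True
        try:
            if undirected:
                g.add_edge(parts[0], parts[1], w)
            else:
                g.add_arc(parts[0], parts[1], w)
        except ValueError as exc:
            raise GraphFormatError(f"line {lineno}: {exc}") from None
    if len(g) == 0:
        raise GraphFormatError("empty graph: no nodes parsed")
    return g


def read_graphml(path, undirected: bool | None = None) -> WeightedDigraph:
    """Load a GraphML file; edge attribute ``weight`` defaults to 1.

    Undirectedness is taken from the GraphML ``edgedefault`` unless
    overridden explicitly.
    """
    gx = nx.read_graphml(path)
    if undirected is None:
        undirected = not gx.is_directed()
    g = WeightedDigraph()
    for v in gx.nodes:
        g.add_node(v)
    for i, j, data in gx.edges(data=True):
        w = as_fraction(data.get("weight", 1))
        if undirected:
            g.add_edge(i, j, w)
        else:
            g.add_arc(i, j, w)
    return g
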