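"""Deterministic fixture graphs and synthetic generators.

These small instances pin down every quantity the framework computes:

* ``example1_graph`` -- three nodes, one undirected edge between nodes 1
  and 2, encoded with gamma = 1/2, beta = 1 so that g(B) is exactly the
  number of edges internal to B.  On this instance the strengths are
  sigma({1,2}) = 1 and sigma(V) = 0, the envelope of V has slopes 3, 2, 1
  with breakpoints at 0 and 1, and the dendrogram is V -> ({1,2}, {3}).
* ``two_pair_digraph`` -- four nodes split into two heavy pairs with
  light cross arcs; the pair with the heavier support "dominates" the
  other in a single envelope minimization, so it exercises the divisive
  recursion that recovers dominated communities.
* ``clique_ring`` -- complete graphs arranged in a ring with unit
  bridges; the classic resolution-limit benchmark: each clique, however
  small relative to its neighbours, is a strong community here
  (sigma(K_m) = m/2 under the edge-count semantics).
* random/planted generators for property tests, seeded and deterministic.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .game import CharacteristicFunction, GameParams
from .graph import WeightedDigraph, as_fraction

__all__ = ["example1_graph", "EDGE_COUNT_PARAMS", "clique_ring",
           "two_pair_digraph", "random_digraph", "planted_partition",
           "named_fixture"]

#: gamma = 1/2 with beta = 1 makes g(B) = (1/2) w(B, B) count undirected
#: edges internal to B when each edge is stored as two opposite arcs.
EDGE_COUNT_PARAMS = GameParams(beta=Fraction(1), gamma=Fraction(1, 2))

#: expected values on the example1 instance, used by validation tooling
EXAMPLE1_EXPECTED = {
    "sigma": {frozenset({"1", "2"}): Fraction(1),
              frozenset({"1", "2", "3"}): Fraction(0),
              frozenset({"1", "3"}): Fraction(0),
              frozenset({"2", "3"}): Fraction(0)},
    "envelope_breakpoints": (Fraction(0), Fraction(1)),
    "first_turning_point": (Fraction(0), Fraction(-1)),
    "support": {(frozenset("12"), frozenset("1")): 1.0,
                (frozenset("123"), frozenset("3")): 0.0},
}


def example1_graph():
    """Three nodes, a single undirected edge {1,2}; g = internal edge count.

    Returns ``(graph, characteristic_function)``.
    """
    g = WeightedDigraph()
    g.add_node("1")
    g.add_node("2")
    g.add_node("3")
    g.add_edge("1", "2", 1)
    return g, CharacteristicFunction.graphical(g, EDGE_COUNT_PARAMS)


def clique_ring(sizes, bridge_weight=1) -> WeightedDigraph:
    """Complete graphs in a ring, consecutive cliques joined by one edge.

    Nodes are labelled ``c<k>n<j>``; the bridge from clique k leaves its
    last node and enters the first node of clique k+1 (wrapping around).
    A single size with zero bridge weight yields a plain clique.
    """
    sizes = list(sizes)
    if any(m < 2 for m in sizes):
        raise ValueError("each clique must have at least 2 nodes")
    bw = as_fraction(bridge_weight)
    if bw < 0:
        raise ValueError("bridge weight must be nonnegative")
    g = WeightedDigraph()
    labels = []
    for k, m in enumerate(sizes):
        block = [f"c{k}n{j}" for j in range(m)]
        labels.append(block)
        for v in block:
            g.add_node(v)
        for a in range(m):
            for b in range(a + 1, m):
                g.add_edge(block[a], block[b], 1)
    if bw > 0 and len(sizes) > 1:
        for k in range(len(sizes)):
            nxt = (k + 1) % len(sizes)
            if len(sizes) == 2 and k == 1:
                break  # two cliques: a single bridge, not a double edge
            g.add_edge(labels[k][-1], labels[nxt][0], bw)
    return g


def clique_nodes(sizes, k) -> frozenset:
    """Node set of the k-th clique generated by :func:`clique_ring`."""
    return frozenset(f"c{k}n{j}" for j in range(list(sizes)[k]))


def two_pair_digraph(strong_w=5, weak_w=1) -> WeightedDigraph:
    """Four-node digraph: heavy pairs {1,2} and {3,4}, light cross arcs.

    Each pair carries bidirectional internal arcs of weight ``strong_w``;
    the pairs are linked by single arcs 2 -> 3 and 4 -> 1 of weight
    ``weak_w``.
    """
    g = WeightedDigraph()
    for v in "1234":
        g.add_node(v)
    g.add_arc("1", "2", strong_w)
    g.add_arc("2", "1", strong_w)
    g.add_arc("3", "4", strong_w)
    g.add_arc("4", "3", strong_w)
    g.add_arc("2", "3", weak_w)
    g.add_arc("4", "1", weak_w)
    return g


def random_digraph(n, density=0.5, max_w=10, seed=None) -> WeightedDigraph:
    """Random digraph with integer weights in 1..max_w (seed mandatory)."""
    if seed is None:
        raise ValueError("random generators require an explicit seed")
    rng = np.random.default_rng(seed)
    g = WeightedDigraph()
    for v in range(1, n + 1):
        g.add_node(str(v))
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if i != j and rng.random() < density:
                g.add_arc(str(i), str(j), int(rng.integers(1, max_w + 1)))
    return g


def planted_partition(k, size, p_in=0.9, p_out=0.05, w_in=1, w_out=1,
                      seed=None) -> WeightedDigraph:
    """Undirected planted-partition benchmark: k blocks of equal size.

    Within-block edges appear with probability ``p_in`` (weight ``w_in``),
    between-block edges with ``p_out`` (weight ``w_out``).
    """
    if seed is None:
        raise ValueError("random generators require an explicit seed")
    rng = np.random.default_rng(seed)
    g = WeightedDigraph()
    labels = [f"b{b}n{j}" for b in range(k) for j in range(size)]
    block = {v: int(v[1 : v.index("n")]) for v in labels}
    for v in labels:
        g.add_node(v)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            u, v = labels[a], labels[b]
            same = block[u] == block[v]
            p, w = (p_in, w_in) if same else (p_out, w_out)
            if rng.random() < p:
                g.add_edge(u, v, w)
    return g


def block_nodes(k, size, b) -> frozenset:
    """Node set of block b generated by :func:`planted_partition`."""
    return frozenset(f"b{b}n{j}" for j in range(size))


_FIXTURES = {
    "example1": lambda: example1_graph()[0],
    "two_pair": lambda: two_pair_digraph(),
    "clique_ring": lambda: clique_ring([20, 5, 20, 5]),
    "clique_ring_small": lambda: clique_ring([5, 3, 5, 3]),
}


def named_fixture(name: str) -> WeightedDigraph:
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
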