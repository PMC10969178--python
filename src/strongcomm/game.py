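"""Convex-game characteristic functions on node sets.

The model: nodes of a weighted digraph are players of a transferable-
utility cooperative game whose characteristic function is

    g(B) = gamma * beta * w(B, B)  -  gamma * (1 - beta) * w(V \\ B, B),

with beta in [0, 1] trading off internal weight against incoming weight
from outside, and gamma > 0 an overall scale.  g is normalized
(g(empty) = 0) and supermodular, so the game is convex and its core is
nonempty.  Arbitrary user-supplied normalized supermodular set functions
are supported through the same interface as black-box oracles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable

from .graph import WeightedDigraph, as_fraction

__all__ = [
    "GameParams",
    "CharacteristicFunction",
    "f_alpha",
    "check_supermodular",
    "maximal_family",
    "minimal_family",
    "subsets",
]

#: absolute tolerance for equality tests in the (rare) float regime
FLOAT_TOL = 1e-9

#: default cap on ground-set size for exhaustive subset enumeration
ENUM_BOUND = 12


@dataclass(frozen=True)
class GameParams:
    """Parameters (beta, gamma) of the graphical characteristic function."""

    beta: Fraction
    gamma: Fraction

    def __post_init__(self):
        object.__setattr__(self, "beta", as_fraction(self.beta))
        object.__setattr__(self, "gamma", as_fraction(self.gamma))
        if not (0 <= self.beta <= 1):
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


class OracleContractError(ValueError):
    """A black-box characteristic function violated its contract."""


class CharacteristicFunction:
    """Normalized (super)modular set function B |-> g(B) on a ground set.

    Either *graphical* -- derived from a :class:`WeightedDigraph` and
    :class:`GameParams`, supermodular by construction -- or a black-box
    oracle, whose supermodularity is checked only on demand
    (:func:`check_supermodular`).
    """

    def __init__(self, ground: Iterable[str], func: Callable[[frozenset], object],
                 graph: WeightedDigraph | None = None,
                 params: GameParams | None = None):
        self.ground = frozenset(str(v) for v in ground)
        self._func = func
        self.graph = graph
        self.params = params
        self._cache: dict[frozenset, object] = {}
        z = func(frozenset())
        if not _is_zero(z):
            raise OracleContractError(f"g(empty set) must be 0, oracle returned {z}")

    # -- constructors --------------------------------------------------

    @classmethod
    def graphical(cls, graph: WeightedDigraph, params: GameParams
                  ) -> "CharacteristicFunction":
        V = graph.node_set
        beta, gamma = params.beta, params.gamma

        def g(B: frozenset) -> Fraction:
            if not B:
                return Fraction(0)
            internal = Fraction(0)
            incoming = Fraction(0)
            for (i, j), a in graph.arcs.items():
                if j in B:
                    if i in B:
                        internal += a
                    else:
                        incoming += a
            return gamma * beta * internal - gamma * (1 - beta) * incoming

        return cls(V, g, graph=graph, params=params)

    @classmethod
    def from_oracle(cls, ground: Iterable[str], func: Callable
                    ) -> "CharacteristicFunction":
        return cls(ground, lambda B: func(B))

    # -- evaluation ----------------------------------------------------

    @property
    def is_graphical(self) -> bool:
        return self.graph is not None

    def __call__(self, B: Iterable[str]):
        B = frozenset(str(v) for v in B)
        extra = B - self.ground
        if extra:
            raise KeyError(f"unknown node identifier: {sorted(extra)[0]!r}")
        if not B:
            return Fraction(0)
        if B not in self._cache:
            self._cache[B] = self._func(B)
        return self._cache[B]

    def marginal(self, B: Iterable[str], i) -> object:
        """g(B u {i}) - g(B)."""
        B = frozenset(str(v) for v in B)
        return self(B | {str(i)}) - self(B)

    def node_order(self) -> list[str]:
        """Ground set in the deterministic dense-index order."""
        if self.graph is not None:
            return [v for v in self.graph.nodes if v in self.ground]
        return sorted(self.ground)

    def sort_key(self):
        """Key ordering nodes by dense index (graphical) or lexicographically."""
        if self.graph is not None:
            return self.graph.index
        return lambda v: v


def _is_zero(x) -> bool:
    if isinstance(x, (int, Fraction)):
        return x == 0
    return abs(x) <= FLOAT_TOL


def f_alpha(cf: CharacteristicFunction, alpha, B: Iterable[str]):
    """The parametric objective f_alpha(B) = alpha * |B| - g(B)."""
    B = frozenset(str(v) for v in B)
    return as_fraction(alpha) * len(B) - cf(B)


def subsets(pool: Iterable[str], min_size: int = 0, max_size: int | None = None):
    """Yield frozenset subsets of *pool* by increasing size (deterministic)."""
    pool = sorted(set(str(v) for v in pool))
    hi = len(pool) if max_size is None else max_size
    for k in range(min_size, hi + 1):
        for combo in itertools.combinations(pool, k):
            yield frozenset(combo)


def check_supermodular(cf: CharacteristicFunction, bound: int = ENUM_BOUND):
    """Exhaustively test g(B) + g(C) <= g(B u C) + g(B n C).

    Uses the equivalent local-exchange form -- for every A and distinct
    i, j outside A, the marginal of i must not decrease when j joins --
    which covers all pairs (B, C) while touching each subset once.
    Returns ``(True, None)`` or ``(False, (B, C))`` with a violating pair.
    """
    V = sorted(cf.ground)
    if len(V) > bound:
        raise ValueError(
            f"ground set has {len(V)} nodes, above the enumeration bound "
            f"{bound}; supermodularity can only be checked exhaustively"
        )
    for A in subsets(V):
        rest = [v for v in V if v not in A]
        for i, j in itertools.combinations(rest, 2):
            Ai, Aj = A | {i}, A | {j}
            lhs = cf(Ai) + cf(Aj)
            rhs = cf(Ai | {j}) + cf(A)
            if _violates(lhs, rhs):
                return False, (Ai, Aj)
    return True, None


def _violates(lhs, rhs) -> bool:
    if isinstance(lhs, Fraction) and isinstance(rhs, Fraction):
        return lhs > rhs
    return float(lhs) > float(rhs) + FLOAT_TOL


def maximal_family(F: Iterable[frozenset]) -> frozenset:
    """Inclusion-wise maximal members of a family (order-independent)."""
    F = set(frozenset(B) for B in F)
    return frozenset(B for B in F if not any(B < C for C in F))


def minimal_family(F: Iterable[frozenset]) -> frozenset:
    """Inclusion-wise minimal members of a family (order-independent)."""
    F = set(frozenset(B) for B in F)
    return frozenset(B for B in F if not any(C < B for C in F))
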