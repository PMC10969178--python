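"""Exact reference implementations of every game-theoretic definition.

Everything here enumerates subsets or solves small linear programs and is
deliberately exponential in |C|: these routines are the ground truth that
the polynomial engines (:mod:`strongcomm.sfm`, :mod:`strongcomm.maxflow`)
are validated against.  They refuse ground sets above an enumeration
bound instead of silently running forever.

Definitions implemented:

* community support to B within C: max over core allocations of the
  minimum (equivalently average) payoff to members of B;
* community strength  sigma(C) = min_{0 != B < C} (g(C) - g(B)) / |C \\ B|,
  the dual form equal to the minimum community support;
* the lower envelope  fhat_alpha(C) = min_{0 != B <= C} (alpha |B| - g(B)),
  a concave piecewise-linear curve whose first turning point sits at
  alpha = sigma(C);
* strong communities  C_alpha(V): inclusion-maximal sets of size >= 2
  with sigma strictly above alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from .game import (
    CharacteristicFunction,
    f_alpha,
    maximal_family,
    minimal_family,
    subsets,
    ENUM_BOUND,
)

__all__ = [
    "StrengthCertificate",
    "PiecewiseCurve",
    "community_support_lp",
    "community_support_avg_lp",
    "sigma_exact",
    "envelope_exact",
    "strong_communities_exact",
    "core_feasible",
]

LP_TOL = 1e-7


class NonConvexGameError(RuntimeError):
    """The core turned out empty: the characteristic function is not supermodular."""


def _check_bound(C, bound):
    if len(C) > bound:
        raise ValueError(
            f"|C| = {len(C)} exceeds the enumeration bound {bound}; "
            "use the sfm or maxflow engine for larger inputs"
        )


@dataclass(frozen=True)
class StrengthCertificate:
    """sigma(C) with the family of subsets attaining the minimum ratio.

    ``witness`` is the lexicographically smallest optimizer by sorted
    dense node index, making reported certificates deterministic.
    """

    set: frozenset
    sigma: object  # Fraction or float
    optimizers: frozenset = field(default_factory=frozenset)
    witness: frozenset | None = None


@dataclass(frozen=True)
class Piece:
    """One linear piece of the envelope, active on [lo, hi)."""

    lo: object  # -inf for the leftmost piece
    hi: object  # +inf for the rightmost
    slope: int
    intercept: object  # equals -max g over active sets
    minimizers: frozenset  # minimal-minimizer family B*_alpha on the piece


@dataclass(frozen=True)
class PiecewiseCurve:
    """Concave lower envelope of the lines alpha |B| - g(B), B nonempty.

    Slopes strictly decrease from |C| on the leftmost piece to 1 on the
    rightmost; ``pieces[i]`` covers the half-open interval
    [breakpoints[i-1], breakpoints[i]) and carries the minimal-minimizer
    family of the interval *interior*.  Exactly at a breakpoint the tying
    lines of the adjacent pieces enlarge the argmin set, so
    :meth:`minimizers_at` re-evaluates the family exactly there: nested
    ties collapse onto the smaller sets, but an incomparable (disjoint)
    set active only at the tie point legitimately joins the family.
    """

    set: frozenset
    breakpoints: tuple
    pieces: tuple  # of Piece, len == len(breakpoints) + 1
    size_groups: dict  # |B| -> (max g over that size, tuple of argmax sets)

    def value(self, alpha):
        p = self.piece_at(alpha)
        return alpha * p.slope + p.intercept

    def piece_at(self, alpha) -> Piece:
        i = 0
        while i < len(self.breakpoints) and alpha >= self.breakpoints[i]:
            i += 1
        return self.pieces[i]

    def minimizers_at(self, alpha) -> frozenset:
        """Exact minimal-minimizer family B*_alpha at one threshold."""
        vals = {k: alpha * k - G for k, (G, _) in self.size_groups.items()}
        m = min(vals.values())
        fam = [B for k, v in vals.items() if v == m
               for B in self.size_groups[k][1]]
        return minimal_family(fam)

    def first_turning_point(self):
        """(alpha, envelope value) of the smallest-alpha breakpoint."""
        a = self.breakpoints[0]
        return a, self.value(a)


def _witness(cf: CharacteristicFunction, family) -> frozenset | None:
    if not family:
        return None
    key = cf.sort_key()
    return min(family, key=lambda B: (len(B), sorted(key(v) for v in B)))


# ----------------------------------------------------------------------
# Core linear programs
# ----------------------------------------------------------------------

def _core_constraints(cf, C):
    """(A_ub, b_ub, A_eq, b_eq) over payoff variables r_i, i in C."""
    C = sorted(C, key=cf.sort_key())
    idx = {v: k for k, v in enumerate(C)}
    n = len(C)
    A_ub, b_ub = [], []
    for B in subsets(C, 1, n - 1):
        row = np.zeros(n)
        for v in B:
            row[idx[v]] = -1.0
        A_ub.append(row)
        b_ub.append(-float(cf(B)))
    A_eq = [np.ones(n)]
    b_eq = [float(cf(C))]
    return C, idx, np.array(A_ub), np.array(b_ub), np.array(A_eq), np.array(b_eq)


def community_support_lp(cf: CharacteristicFunction, C, B,
                         bound: int = ENUM_BOUND) -> float:
    """Max over core(C, g) of the minimum payoff among members of B.

    LP: maximize m subject to m <= r_i for i in B, r(C) = g(C) and
    r(B') >= g(B') for every nonempty B' < C.
    """
    C = frozenset(str(v) for v in C)
    B = frozenset(str(v) for v in B)
    if not B or not B < C or len(C) < 2:
        raise ValueError("require nonempty B strictly inside C, |C| >= 2")
    _check_bound(C, bound)
    Cs, idx, A_ub, b_ub, A_eq, b_eq = _core_constraints(cf, C)
    n = len(Cs)
    # variables: r_0..r_{n-1}, m
    A_ub = np.hstack([A_ub, np.zeros((A_ub.shape[0], 1))])
    rows, rhs = [], []
    for v in B:
        row = np.zeros(n + 1)
        row[idx[v]] = -1.0
        row[n] = 1.0  # m - r_v <= 0
        rows.append(row)
        rhs.append(0.0)
    A_ub = np.vstack([A_ub, rows])
    b_ub = np.concatenate([b_ub, rhs])
    A_eq = np.hstack([A_eq, np.zeros((1, 1))])
    c = np.zeros(n + 1)
    c[n] = -1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(None, None)] * (n + 1), method="highs")
    if res.status != 0:
        raise NonConvexGameError(f"core LP failed (status {res.status}): {res.message}")
    return -res.fun


def community_support_avg_lp(cf: CharacteristicFunction, C, B,
                             bound: int = ENUM_BOUND) -> float:
    """Max over core(C, g) of the average payoff r(B) / |B|."""
    C = frozenset(str(v) for v in C)
    B = frozenset(str(v) for v in B)
    if not B or not B < C or len(C) < 2:
        raise ValueError("require nonempty B strictly inside C, |C| >= 2")
    _check_bound(C, bound)
    Cs, idx, A_ub, b_ub, A_eq, b_eq = _core_constraints(cf, C)
    c = np.zeros(len(Cs))
    for v in B:
        c[idx[v]] = -1.0 / len(B)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(None, None)] * len(Cs), method="highs")
    if res.status != 0:
        raise NonConvexGameError(f"core LP failed (status {res.status}): {res.message}")
    return -res.fun


def core_feasible(cf: CharacteristicFunction, C, bound: int = ENUM_BOUND) -> bool:
    """Is the core of the subgame on C nonempty?  (Always true when convex.)"""
    C = frozenset(str(v) for v in C)
    _check_bound(C, bound)
    if len(C) < 2:
        return True
    Cs, idx, A_ub, b_ub, A_eq, b_eq = _core_constraints(cf, C)
    res = linprog(np.zeros(len(Cs)), A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                  b_eq=b_eq, bounds=[(None, None)] * len(Cs), method="highs")
    return res.status == 0


# ----------------------------------------------------------------------
# Strength by enumeration
# ----------------------------------------------------------------------

def sigma_exact(cf: CharacteristicFunction, C,
                bound: int = ENUM_BOUND) -> StrengthCertificate:
    """sigma(C) = min over nonempty proper B of (g(C) - g(B)) / |C \\ B|.

    Enumerates all 2^|C| - 2 candidates and returns the complete argmin
    family together with the deterministic witness.
    """
    C = frozenset(str(v) for v in C)
    if len(C) < 2:
        raise ValueError("community strength is defined only for |C| >= 2")
    _check_bound(C, bound)
    gC = cf(C)
    best = None
    argmin: list[frozenset] = []
    for B in subsets(C, 1, len(C) - 1):
        ratio = (gC - cf(B)) / Fraction(len(C) - len(B))
        if best is None or ratio < best:
            best, argmin = ratio, [B]
        elif ratio == best:
            argmin.append(B)
    family = frozenset(argmin)
    return StrengthCertificate(set=C, sigma=best, optimizers=family,
                               witness=_witness(cf, family))


def envelope_exact(cf: CharacteristicFunction, C,
                   bound: int = ENUM_BOUND) -> PiecewiseCurve:
    """Exact lower envelope of all 2^|C| - 1 lines alpha |B| - g(B)."""
    C = frozenset(str(v) for v in C)
    if not C:
        raise ValueError("empty ground set has no envelope")
    _check_bound(C, bound)
    by_size: dict[int, list[frozenset]] = {}
    G: dict[int, object] = {}  # max g over sets of each size
    for B in subsets(C, 1, len(C)):
        k = len(B)
        gB = cf(B)
        if k not in G or gB > G[k]:
            G[k] = gB
            by_size[k] = [B]
        elif gB == G[k]:
            by_size[k].append(B)

    # lower envelope of the lines (slope k, intercept -G[k]):
    # scan slopes descending (leftmost piece has the largest slope).
    slopes = sorted(G, reverse=True)
    hull: list[int] = [slopes[0]]  # active slopes left to right
    bps: list = []  # breakpoint between hull[i] and hull[i+1]
    for k in slopes[1:]:
        while True:
            k0 = hull[-1]
            # intersection of the slope-k0 and slope-k lines
            a = (G[k0] - G[k]) / Fraction(k0 - k)
            if bps and a <= bps[-1]:
                # top line is never strictly below the rest: discard
                hull.pop()
                bps.pop()
            else:
                hull.append(k)
                bps.append(a)
                break

    size_groups = {k: (G[k], tuple(by_size[k])) for k in G}

    def interior_family(k):
        # within one piece the argmin lines all have the active slope
        return minimal_family(by_size[k])

    pieces = []
    for i, k in enumerate(hull):
        lo = bps[i - 1] if i > 0 else -_inf_like()
        hi = bps[i] if i < len(bps) else _inf_like()
        pieces.append(Piece(lo=lo, hi=hi, slope=k, intercept=-G[k],
                            minimizers=interior_family(k)))
    return PiecewiseCurve(set=C, breakpoints=tuple(bps), pieces=tuple(pieces),
                          size_groups=size_groups)


def _inf_like():
    return float("inf")


def strong_communities_exact(cf: CharacteristicFunction, V, alpha,
                             bound: int = ENUM_BOUND) -> frozenset:
    """C_alpha(V): maximal subsets of size >= 2 with sigma strictly > alpha."""
    V = frozenset(str(v) for v in V)
    _check_bound(V, bound)
    strong = [C for C in subsets(V, 2, len(V))
              if sigma_exact(cf, C, bound).sigma > alpha]
    return maximal_family(strong)


def sigma_via_core_lp(cf: CharacteristicFunction, C, average: bool = False,
                      bound: int = ENUM_BOUND) -> float:
    """sigma(C) straight from its definition: minimum community support.

    Cross-check route (float, LP-based); ``average=True`` uses the
    average-payoff form, which provably gives the same value.
    """
    C = frozenset(str(v) for v in C)
    if len(C) < 2:
        raise ValueError("community strength is defined only for |C| >= 2")
    _check_bound(C, bound)
    fn = community_support_avg_lp if average else community_support_lp
    return min(fn(cf, C, B, bound) for B in subsets(C, 1, len(C) - 1))
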