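"""Polynomial-time engines for envelope minimization and strength.

The object being minimized is the submodular function

    h(A) = alpha |A| - g_t(A),     g_t(A) = g(A u {t}) - g({t}),

over subsets A of C \\ {t} (the anchored reduction: g(B) - g_t(B \\ {t})
is the constant g({t}) for every B containing t, so minimizers
translate back as B = A u {t}).  Three interchangeable back-ends solve
it:

``bruteforce``
    exhaustive enumeration (ground sets up to the enumeration bound);
``mnp``
    Fujishige-Wolfe minimum-norm-point on the base polytope with the
    greedy linear-optimization oracle; the float min-norm base orders
    the ground set, and every threshold ("prefix") set of that order is
    re-scored in exact arithmetic before one is accepted -- in exact
    arithmetic the minimal minimizer is the strictly-negative support
    of the base, which is always such a prefix;
``maxflow``
    the augmented-digraph min-cut (graphical g, alpha >= 0 only).

``auto`` picks maxflow when applicable, otherwise brute force at oracle
scale and the minimum-norm-point solver beyond it.

On top of the anchored solver sit: the minimal-minimizer family
B*_alpha (union of the anchored minimizers over the anchors attaining
the global envelope minimum), the discrete-Newton (Dinkelbach) iteration
for sigma(C), and the certified line-intersection recursion recovering
every breakpoint of an anchor's nested minimizer sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .game import (
    CharacteristicFunction,
    ENUM_BOUND,
    FLOAT_TOL,
    f_alpha,
    minimal_family,
)
from .graph import as_fraction
from .oracle import StrengthCertificate, _witness

__all__ = ["min_f_alpha_with_t", "b_star", "sigma_fast", "sigma",
           "breakpoints_for_t", "BreakpointSequence", "ENGINES"]

ENGINES = ("auto", "bruteforce", "sfm", "mnp", "maxflow")


def _exact(x) -> bool:
    return isinstance(x, (int, Fraction))


def _eq(a, b) -> bool:
    if _exact(a) and _exact(b):
        return a == b
    return abs(float(a) - float(b)) <= FLOAT_TOL


def _lt(a, b) -> bool:
    if _exact(a) and _exact(b):
        return a < b
    return float(a) < float(b) - FLOAT_TOL


# ----------------------------------------------------------------------
# Anchored minimization: dispatch
# ----------------------------------------------------------------------

def min_f_alpha_with_t(cf: CharacteristicFunction, C, t, alpha,
                       engine: str = "auto") -> frozenset:
    """Unique inclusion-minimal minimizer of f_alpha over {B : t in B <= C}."""
    B, _ = _anchored_min(cf, C, t, alpha, engine, strict_engine=True)
    return B


def _anchored_min(cf, C, t, alpha, engine, strict_engine=False):
    C = frozenset(str(v) for v in C)
    t = str(t)
    if t not in C:
        raise ValueError(f"anchor {t!r} not in C")
    alpha = as_fraction(alpha)
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; pick one of {ENGINES}")

    if engine == "maxflow":
        if not cf.is_graphical:
            raise ValueError("maxflow engine requires a graphical characteristic function")
        if alpha < 0:
            if strict_engine:
                raise ValueError(
                    "maxflow engine handles alpha >= 0 only; "
                    "use engine='sfm' for negative thresholds"
                )
            engine = "sfm"  # hint mode: silent fallback
    if engine == "auto":
        if cf.is_graphical and alpha >= 0:
            engine = "maxflow"
        else:
            engine = "sfm"
    if engine == "sfm":
        engine = "bruteforce" if len(C) - 1 <= ENUM_BOUND else "mnp"

    if engine == "maxflow":
        from . import maxflow
        B = maxflow.anchored_min_cut(cf.graph, cf.params, C, t, alpha)
    elif engine == "bruteforce":
        B = _brute_anchored(cf, C, t, alpha)
    else:
        B = _mnp_anchored(cf, C, t, alpha)
    return B, f_alpha(cf, alpha, B)


def _brute_anchored(cf, C, t, alpha):
    """Minimal minimizer by enumeration: intersection of all argmins."""
    from .game import subsets

    rest = C - {t}
    best = None
    inter = None
    for A in subsets(rest):
        B = A | {t}
        v = f_alpha(cf, alpha, B)
        if best is None or _lt(v, best):
            best, inter = v, set(B)
        elif _eq(v, best):
            inter &= B
    B = frozenset(inter)
    # lattice property: the intersection of minimizers is itself a minimizer
    assert _eq(f_alpha(cf, alpha, B), best), "minimizers do not form a lattice"
    return B


# ----------------------------------------------------------------------
# Fujishige-Wolfe minimum-norm point
# ----------------------------------------------------------------------

def _mnp_anchored(cf, C, t, alpha):
    ground = sorted(C - {t}, key=cf.sort_key())
    if not ground:
        return frozenset({t})
    gt = cf({t})
    af = float(alpha)

    def h_float(prefix_members):
        A = frozenset(prefix_members)
        return af * len(A) - float(cf(A | {t}) - gt)

    def greedy(x):
        """Base-polytope vertex minimizing <x, q> (greedy on ascending x)."""
        order = sorted(range(len(ground)), key=lambda i: (x[i], i))
        q = np.empty(len(ground))
        prev = 0.0
        acc = []
        for i in order:
            acc.append(ground[i])
            cur = h_float(acc)
            q[i] = cur - prev
            prev = cur
        return q

    x = _wolfe_mnp(greedy, len(ground))
    # exact re-scoring of the threshold sets of the min-norm base
    order = sorted(range(len(ground)), key=lambda i: (x[i], i))
    best_val = None
    best_set = None
    acc: list[str] = []
    candidates = [frozenset()]
    for i in order:
        acc.append(ground[i])
        candidates.append(frozenset(acc))
    for A in candidates:
        v = f_alpha(cf, alpha, A | {t})
        if best_val is None or _lt(v, best_val) or (
                _eq(v, best_val) and len(A) < len(best_set)):
            best_val, best_set = v, A
    return frozenset(best_set) | {t}


def _wolfe_mnp(linopt, n, eps=1e-10, max_iter=300):
    """Wolfe's algorithm for the minimum-norm point of a polytope.

    ``linopt(x)`` returns a vertex minimizing <x, q>.  Returns the
    (approximate) minimum-norm point over the convex hull of vertices.
    """
    q = linopt(np.zeros(n))
    S = [q]
    lam = np.array([1.0])
    x = q.copy()
    for _ in range(max_iter):
        q = linopt(x)
        if float(x @ x) - float(x @ q) <= eps * (1.0 + float(x @ x)):
            break
        if any(np.allclose(q, s, atol=1e-12) for s in S):
            break
        S.append(q)
        lam = np.append(lam, 0.0)
        # minor cycle: affine minimization with reinsertion
        for _ in range(10 * n + 10):
            A = np.array(S).T  # n x m
            m = A.shape[1]
            M = A.T @ A + 1e-12 * np.eye(m)
            try:
                y = np.linalg.solve(M, np.ones(m))
            except np.linalg.LinAlgError:  # pragma: no cover
                y, *_ = np.linalg.lstsq(M, np.ones(m), rcond=None)
            mu = y / y.sum()
            if np.all(mu > 1e-11):
                lam = mu
                x = A @ mu
                break
            # step toward the affine minimizer until a coefficient dies
            diffs = lam - mu
            with np.errstate(divide="ignore", invalid="ignore"):
                theta = np.min(np.where(diffs > 1e-14, lam / diffs, np.inf))
            theta = min(1.0, float(theta))
            lam = lam + theta * (mu - lam)
            lam[lam < 1e-11] = 0.0
            keep = lam > 0
            if keep.sum() == 0:  # pragma: no cover
                keep[int(np.argmax(mu))] = True
            S = [s for s, k in zip(S, keep) if k]
            lam = lam[keep]
            lam = lam / lam.sum()
            x = np.array(S).T @ lam
        else:  # pragma: no cover
            break
    return x


# ----------------------------------------------------------------------
# Minimal-minimizer family, strength, breakpoints
# ----------------------------------------------------------------------

def b_star(cf: CharacteristicFunction, C, alpha, engine: str = "auto"
           ) -> frozenset:
    """B*_alpha(C): inclusion-minimal minimizers of f_alpha over nonempty B.

    One anchored solve per node; anchors attaining the overall minimum
    contribute their (unique minimal) minimizers, whose inclusion-minimal
    union is the family.  Members are pairwise disjoint.
    """
    C = frozenset(str(v) for v in C)
    if not C:
        raise ValueError("empty ground set")
    alpha = as_fraction(alpha)
    best_val = None
    winners: list[frozenset] = []
    for t in sorted(C, key=cf.sort_key()):
        B, v = _anchored_min(cf, C, t, alpha, engine)
        if best_val is None or _lt(v, best_val):
            best_val, winners = v, [B]
        elif _eq(v, best_val):
            winners.append(B)
    return minimal_family(winners)


def sigma_fast(cf: CharacteristicFunction, C, engine: str = "auto"
               ) -> StrengthCertificate:
    """sigma(C) by discrete-Newton (Dinkelbach) iteration on the ratio
    (g(C) - g(B)) / |C \\ B|.

    Starts from the feasible ratio of a singleton-complement, so every
    iterate satisfies alpha >= sigma(C); each step replaces alpha by the
    best ratio among the current minimal minimizers, strictly shrinking
    the active sets, and terminates (in at most |C| steps) when the
    envelope minimum ties f_alpha(C) -- i.e. at alpha = sigma(C).  The
    certificate's optimizer family is the inclusion-minimal part of the
    argmin family S(C).
    """
    C = frozenset(str(v) for v in C)
    if len(C) < 2:
        raise ValueError("community strength is defined only for |C| >= 2")
    gC = cf(C)
    i0 = max(C, key=cf.sort_key())
    alpha = (gC - cf(C - {i0})) / Fraction(1)
    for _ in range(len(C) + 2):
        fam = b_star(cf, C, alpha, engine)
        env = f_alpha(cf, alpha, next(iter(fam)))
        fC = f_alpha(cf, alpha, C)
        if _eq(env, fC):
            proper = frozenset(B for B in fam if B != C)
            if proper:  # alpha == sigma(C)
                return StrengthCertificate(set=C, sigma=alpha,
                                           optimizers=proper,
                                           witness=_witness(cf, proper))
            raise RuntimeError(
                "discrete-Newton iterate fell below sigma; "
                "inconsistent characteristic function evaluations"
            )
        # alpha > sigma: tighten to the best ratio among current minimizers
        alpha = min((gC - cf(B)) / Fraction(len(C) - len(B)) for B in fam)
    raise RuntimeError("discrete-Newton failed to converge in |C| steps")


def sigma(cf: CharacteristicFunction, C, engine: str = "auto"
          ) -> StrengthCertificate:
    """Strength of C via the engine of choice (oracle for ``bruteforce``)."""
    if engine == "bruteforce":
        from .oracle import sigma_exact
        return sigma_exact(cf, C)
    return sigma_fast(cf, C, engine)


@dataclass(frozen=True)
class BreakpointSequence:
    """All breakpoints of one anchor's minimal-minimizer map.

    ``sets[i]`` (each containing the anchor) is the minimal minimizer on
    the half-open interval [breakpoints[i-1], breakpoints[i]); the
    sequence is strictly nested from the full ground set down to the
    anchor singleton.
    """

    anchor: str
    breakpoints: tuple
    sets: tuple  # len == len(breakpoints) + 1

    def set_at(self, alpha) -> frozenset:
        i = 0
        while i < len(self.breakpoints) and alpha >= self.breakpoints[i]:
            i += 1
        return self.sets[i]


def breakpoints_for_t(cf: CharacteristicFunction, C, t,
                      engine: str = "auto") -> BreakpointSequence:
    """Recover the full nested breakpoint sequence of one anchor.

    Certified line-intersection search: the bracketing thresholds where
    the minimizer is provably the full set / the anchor singleton come
    from the extreme marginals of g (monotone by supermodularity); the
    recursion probes the intersection of the two bracketing lines and
    splits until adjacent intervals are certified.  About two anchored
    solves per breakpoint.
    """
    C = frozenset(str(v) for v in C)
    t = str(t)
    if t not in C:
        raise ValueError(f"anchor {t!r} not in C")
    rest = C - {t}
    if not rest:
        return BreakpointSequence(anchor=t, breakpoints=(),
                                  sets=(frozenset({t}),))
    # certified bracket from extreme marginals (monotone for supermodular g)
    margins_lo = [cf({t, i}) - cf({t}) for i in rest]
    margins_hi = [cf(C) - cf(C - {i}) for i in rest]
    a_lo = min(margins_lo) - 1
    a_hi = max(margins_hi) + 1

    def solve(a):
        # bracket endpoints may be negative: never hard-fail on engine domain
        return _anchored_min(cf, C, t, a, engine)[0]

    B_lo, B_hi = C, frozenset({t})
    found: list[tuple] = []  # (alpha, right set)

    def rec(a1, B1, a2, B2):
        if B1 == B2:
            return
        am = (cf(B1) - cf(B2)) / Fraction(len(B1) - len(B2))
        Bm = solve(am)
        vm = f_alpha(cf, am, Bm)
        v1 = f_alpha(cf, am, B1)
        if _eq(vm, v1):
            # single breakpoint between B1 and B2 at their line crossing
            found.append((am, B2))
        else:
            rec(a1, B1, am, Bm)
            rec(am, Bm, a2, B2)

    rec(a_lo, B_lo, a_hi, B_hi)
    found.sort(key=lambda p: p[0])
    bps = tuple(a for a, _ in found)
    sets = (C,) + tuple(B for _, B in found)
    for big, small in zip(sets, sets[1:]):
        if not small < big:
            raise AssertionError("breakpoint minimizers are not strictly nested")
    return BreakpointSequence(anchor=t, breakpoints=bps, sets=sets)
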