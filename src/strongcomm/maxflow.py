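"""Anchored envelope minimization as a minimum s-t cut.

For a graphical characteristic function and alpha >= 0, the anchored
problem

    min { alpha |B| - g(B)  :  t in B subseteq C }

is solved by one max-flow computation on an augmented digraph: a fresh
source s is wired to every node of C with capacity alpha (plus a modular
correction when C is a strict subset of the global ground set), arcs
into the anchor t are boosted by beta times the within-C in-weight of
their tail, and the minimum s-t cut with inclusion-minimal sink side is
exactly the minimal minimizer.  The correspondence is the cut identity

    cut({s} u (C \\ B), B)  =  f_alpha(B) + beta * w(C, C),

which holds for every B containing t (and is tested exhaustively).

General gamma is handled by rescaling: minimizers of alpha |B| - gamma
g1(B) coincide with minimizers of (alpha / gamma) |B| - g1(B), so the
engine divides alpha by gamma and never touches capacities.  alpha < 0
would need negative source capacities and is outside this engine's
domain; callers fall back to the SFM engine there.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_flow

from .game import CharacteristicFunction, GameParams
from .graph import WeightedDigraph, as_fraction

__all__ = ["AugmentedDigraph", "build_augmented", "min_cut_minimal_sink",
           "anchored_min_cut", "parametric_sweep"]

SOURCE = object()  # sentinel source label, distinct from any node id

#: capacities are scaled to integers for the exact scipy solver as long
#: as the scaled magnitudes stay comfortably inside int64
_INT_LIMIT = 2 ** 58


@dataclass(frozen=True)
class AugmentedDigraph:
    """The (alpha, beta, t)-augmented flow network over {s} u C."""

    C: tuple  # nodes in dense-index order
    t: str
    alpha: Fraction  # already divided by gamma
    beta: Fraction
    capacities: dict  # (u, v) -> Fraction, u/v in C or SOURCE
    offset: Fraction  # beta * w(C, C), the constant in the cut identity

    def cut_value(self, B) -> Fraction:
        """Capacity of the directed cut ({s} u (C \\ B), B) for t in B."""
        B = frozenset(str(v) for v in B)
        if self.t not in B:
            raise ValueError("sink side must contain the anchor t")
        total = Fraction(0)
        for (u, v), cap in self.capacities.items():
            u_src = u is SOURCE or u not in B
            if u_src and v in B:
                total += cap
        return total


def build_augmented(graph: WeightedDigraph, params: GameParams, C, t,
                    alpha) -> AugmentedDigraph:
    """Construct the augmented digraph for the anchored minimization on C.

    ``d_i`` is the weighted in-degree of i within C, so that the boosted
    arcs into t contribute beta * w(C, C \\ B) to any cut; the source arc
    to j carries alpha plus the modular correction
    (1 - beta) * w(V \\ C, {j}) that keeps g's incoming-weight term global
    when C is a strict subset of V.
    """
    C = frozenset(str(v) for v in C)
    t = str(t)
    if t not in C:
        raise ValueError(f"anchor {t!r} not in C")
    alpha = as_fraction(alpha) / params.gamma
    if alpha < 0:
        raise ValueError(
            "alpha < 0 needs negative source capacities; "
            "use the sfm engine for negative thresholds"
        )
    beta = params.beta
    V = graph.node_set
    outside = V - C
    order = [v for v in graph.nodes if v in C]

    cap: dict = {}
    d = {i: Fraction(0) for i in C}  # within-C in-weight
    m = {j: Fraction(0) for j in C}  # modular correction from outside C
    for (i, j), a in graph.arcs.items():
        if j in C:
            if i in C:
                d[j] += a
                if i != j and j != t:
                    cap[(i, j)] = cap.get((i, j), Fraction(0)) + a
            elif i in outside:
                m[j] += a
    # arcs into the anchor: original weight plus beta * d_i (no self-loop)
    for i in C:
        if i == t:
            continue
        w_it = graph.arcs.get((i, t), Fraction(0))
        boosted = w_it + beta * d[i]
        if boosted > 0:
            cap[(i, t)] = boosted
    for j in C:
        c = alpha + (1 - beta) * m[j]
        if c > 0:
            cap[(SOURCE, j)] = c
    offset = beta * sum((d[i] for i in C), Fraction(0))
    return AugmentedDigraph(C=tuple(order), t=t, alpha=alpha, beta=beta,
                            capacities=cap, offset=offset)


def min_cut_minimal_sink(aug: AugmentedDigraph) -> frozenset:
    """Inclusion-minimal sink side of a minimum s-t cut (always contains t).

    Computed as the set of nodes from which t is reachable in the
    residual graph of a maximum flow.
    """
    index = {SOURCE: 0}
    for k, v in enumerate(aug.C, start=1):
        index[v] = k
    n = len(aug.C) + 1
    t_idx = index[aug.t]

    caps = list(aug.capacities.items())
    denoms = [c.denominator for (_, c) in caps]
    scale = 1
    for dnm in denoms:
        scale = scale * dnm // math.gcd(scale, dnm)
        if scale > _INT_LIMIT:
            break
    max_num = max((abs(c.numerator) for (_, c) in caps), default=0)
    if scale <= _INT_LIMIT and max_num * scale <= _INT_LIMIT:
        reach = _scipy_residual_reach(caps, index, n, t_idx, scale)
    else:  # huge denominators (e.g. irrational-looking floats): float solve
        reach = _float_residual_reach(caps, index, n, t_idx)
    return frozenset(v for v in aug.C if index[v] in reach)


def _scipy_residual_reach(caps, index, n, t_idx, scale):
    rows, cols, vals = [], [], []
    for (u, v), c in caps:
        rows.append(index[u])
        cols.append(index[v])
        vals.append(int(c * scale))
    mat = csr_matrix((np.array(vals, dtype=np.int64),
                      (np.array(rows), np.array(cols))), shape=(n, n))
    res = maximum_flow(mat, 0, t_idx)
    flow = res.flow
    # residual in-edges of v: u with cap(u,v) - flow(u,v) > 0, or flow(v,u) > 0
    radj: list[list[int]] = [[] for _ in range(n)]  # v -> residual tails u
    cap_arr = mat.toarray()
    flow_arr = flow.toarray()
    residual = cap_arr - flow_arr  # reverse arcs: flow negative => residual > 0
    us, vs = np.nonzero(residual > 0)
    for u, v in zip(us.tolist(), vs.tolist()):
        radj[v].append(u)
    return _reverse_bfs(radj, t_idx)


def _float_residual_reach(caps, index, n, t_idx, tol=1e-9):
    import networkx as nx
    from networkx.algorithms.flow import dinitz

    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for (u, v), c in caps:
        G.add_edge(index[u], index[v], capacity=float(c))
    R = dinitz(G, 0, t_idx)
    radj: list[list[int]] = [[] for _ in range(n)]
    for u, v, data in R.edges(data=True):
        if data["capacity"] - data["flow"] > tol:
            radj[v].append(u)
    return _reverse_bfs(radj, t_idx)


def _reverse_bfs(radj, t_idx):
    seen = {t_idx}
    queue = deque([t_idx])
    while queue:
        v = queue.popleft()
        for u in radj[v]:
            if u not in seen:
                seen.add(u)
                queue.append(u)
    return seen


def anchored_min_cut(graph: WeightedDigraph, params: GameParams, C, t,
                     alpha) -> frozenset:
    """Minimal minimizer of alpha |B| - g(B) over t in B subseteq C."""
    aug = build_augmented(graph, params, C, t, alpha)
    return min_cut_minimal_sink(aug)


def parametric_sweep(graph: WeightedDigraph, params: GameParams, C, t,
                     alphas="all"):
    """Breakpoints of the anchored minimal minimizer over alpha >= 0.

    ``alphas="all"`` returns the nonnegative-alpha portion of the
    breakpoint sequence (certified line-intersection recursion, one
    max-flow per probe); an explicit iterable of thresholds returns the
    list of (alpha, minimal minimizer) pairs instead.
    """
    from . import sfm  # deferred: sfm owns the recursion scaffolding

    if alphas == "all":
        seq = sfm.breakpoints_for_t(
            CharacteristicFunction.graphical(graph, params), C, t,
            engine="maxflow")
        keep = [k for k, a in enumerate(seq.breakpoints) if a >= 0]
        if not keep:
            return sfm.BreakpointSequence(anchor=seq.anchor, breakpoints=(),
                                          sets=(seq.sets[-1],))
        first = keep[0]
        return sfm.BreakpointSequence(
            anchor=seq.anchor,
            breakpoints=tuple(seq.breakpoints[k] for k in keep),
            sets=tuple(seq.sets[first:]),
        )
    return [(a, anchored_min_cut(graph, params, C, t, a)) for a in alphas]
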