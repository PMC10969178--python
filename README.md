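# strongcomm

Game-theoretic detection of **strong communities** in weighted directed
networks — biological interaction and regulatory networks, social graphs,
or any system described by a supermodular set function.

Most community-detection methods return non-unique, initialization-dependent
partitions and offer no operational meaning for "community".  `strongcomm`
instead models the nodes of a weighted digraph as players of a convex
cooperative game and scores each candidate community by how much stable
payoff its members can guarantee one another.  The resulting communities
are **unique**, form a **laminar hierarchy** (a dendrogram), are free of
the resolution limit that makes modularity merge small cliques, and are
computable in **polynomial time**.

## The model

For a weighted digraph on nodes `V` with arc weights `a_ij`, write
`w(B, C) = Σ_{i∈B, j∈C} a_ij`.  The characteristic function of the game is

```
g(B) = γ·β·w(B, B) − γ·(1−β)·w(V∖B, B),        β ∈ [0, 1], γ > 0,
```

which rewards internal weight and penalizes weight coming into `B` from
outside.  `g` is normalized and supermodular, so the game is convex and its
core (the stable payoff allocations splitting `g(C)` so that no coalition
is underpaid) is never empty.

The **strength** of a community `C` (|C| ≥ 2) is the worst-case community
support over its sub-coalitions:

```
σ(C) = min_{∅≠B⊊C}  max_{r ∈ Core(C, g)}  min_{i∈B} r_i
     = min_{∅≠B⊊C}  (g(C) − g(B)) / |C ∖ B|          (dual form)
```

**Strong communities at threshold α** are the inclusion-maximal sets with
`σ(C) > α`; they are pairwise disjoint, nest as α varies, and the union over
all α forms a dendrogram in which every internal node carries its σ.

Computation never enumerates subsets: the dual form is the first turning
point of the concave envelope `f̂_α(C) = min_B (α|B| − g(B))`, which is
minimized by submodular function minimization (Fujishige–Wolfe
minimum-norm point), or — for graphical `g` and α ≥ 0 — by a single min-cut
on a source-augmented digraph.  A discrete-Newton iteration on the ratio
recovers σ in at most |C| steps, and a certified line-intersection search
recovers all parametric breakpoints.

## Worked example

The canonical three-node instance: nodes `{1, 2, 3}`, a single undirected
edge between 1 and 2, and `g` = number of internal edges (β = 1, γ = ½).

```console
$ strongcomm synth example1 --out ex1.tsv
$ strongcomm strength ex1.tsv --set 1,2
{"set": ["1", "2"], "sigma": 1.0, "witness": ["1"], "optimizers": [["1"], ["2"]]}
```

σ({1,2}) = 1: the pair's core holds one unit of transferable payoff, so
either member alone is guaranteed payoff 1 — a meaningful community.  The
full node set is much weaker (σ(V) = 0, because the isolated node 3 can be
guaranteed nothing):

```console
$ strongcomm communities ex1.tsv --alpha 0.5
{"alpha": 0.5, "communities": [["1", "2"]], "invocations": 2}
```

At threshold α = ½ only `{1,2}` survives; the divisive recursion needed two
rounds (one that found the pair, one that stopped on the leftover node 3).
The full hierarchy, in Newick with σ annotations:

```console
$ strongcomm hierarchy ex1.tsv --output newick
((1,2)[&sigma=1],3)[&sigma=0];
```

and the envelope curve behind it — slopes 3, 2, 1 with turning points at
α = 0 and α = 1, whose first turning point (0, −1) sits exactly at σ(V):

```console
$ strongcomm curve ex1.tsv
{"set": ["1", "2", "3"], "breakpoints": [0.0, 1.0], "pieces": [
  {"slope": 3, "intercept": -1.0, "minimizers": [["1", "2", "3"]]},
  {"slope": 2, "intercept": -1.0, "minimizers": [["1", "2"]]},
  {"slope": 1, "intercept": 0.0, "minimizers": [["1"], ["2"], ["3"]]}]}
```

The same API is available from Python:

```python
from strongcomm import CharacteristicFunction, build_dendrogram, sigma
from strongcomm.fixtures import example1_graph

graph, cf = example1_graph()
print(sigma(cf, {"1", "2"}).sigma)      # Fraction(1, 1)
root = build_dendrogram(cf)             # dendrogram with exact σ values
```

Arbitrary normalized supermodular set functions plug in through
`CharacteristicFunction.from_oracle(ground, func)` and run on the same
engines (minus the max-flow specialization, which needs graphical `g`).

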