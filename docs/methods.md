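# Methods

## Model and assumptions

A weighted digraph on nodes `V` (arc weights `a_ij ≥ 0`, parallel arcs
merged, self-loops allowed) induces a transferable-utility cooperative
game with characteristic function

    g(B) = γ·β·w(B,B) − γ·(1−β)·w(V∖B, B),

where `w(B,C)` sums `a_ij` over ordered pairs `i∈B, j∈C`.  `g` is
normalized (`g(∅)=0`) and supermodular, hence the game is convex and the
core of every subgame is nonempty.  The strength of `C` (`|C| ≥ 2`) is

    σ(C) = min_{∅≠B⊊C} max_{r∈Core(C,g)} min_{i∈B} r_i
         = min_{∅≠B⊊C} (g(C) − g(B)) / |C∖B|,

where the second (dual) form is what all engines compute; the first is
retained as an LP and used for cross-validation.  Strong communities at
threshold α are `C_α(V) = maximal{C : |C|>1, σ(C) > α}` — note the
*strict* inequality, which is what makes the top-down dendrogram
construction well defined: the children of an internal node `C` are
exactly `C_{σ(C)}(C)` plus a leaf per uncovered node, and `C` itself can
never reappear among them.

Undirected inputs are stored as two opposite arcs of the full edge
weight.  With `β = 1, γ = ½` this makes `g(B)` the number (or total
weight) of undirected edges internal to `B` — the semantics used by the
bundled `example1` fixture and the clique fixtures, under which
`σ(K_m) = m/2`.

Black-box set functions are accepted through the same interface; they
must be normalized, and supermodularity is only checkable on demand
(exhaustively, ground sets ≤ 12 by default, via the equivalent
local-exchange form of the inequality).

## Engines

Every computation reduces to anchored envelope minimizations

    min { α|B| − g(B) : t ∈ B ⊆ C },

whose objective, after contracting the anchor (`g_t(A) = g(A∪{t}) −
g({t})`), is submodular on `C∖{t}`.  Three back-ends solve it:

* **bruteforce** — exhaustive enumeration; the unique inclusion-minimal
  minimizer is the intersection of all argmins (minimizers form a
  lattice).  Used automatically for ground sets within the enumeration
  bound and as the reference in tests.
* **mnp** — Fujishige–Wolfe minimum-norm point on the base polytope with
  the greedy (sort-based) linear oracle.  The float min-norm base is used
  only to *order* the ground set; every threshold ("prefix") set of that
  order is then re-scored in exact rational arithmetic and the smallest
  exact argmin is returned.  In exact arithmetic the minimal minimizer is
  the strictly-negative support of the base and is always such a prefix,
  so the hybrid scheme inherits MNP's speed without its tie fragility.
* **maxflow** — for graphical `g` and α ≥ 0, one min-cut on the
  (α, β, t)-augmented digraph: a fresh source `s` feeds every node `j∈C`
  with capacity `α + (1−β)·w(V∖C,{j})` (the modular correction that keeps
  `g` global when recursing on a sub-instance `C ⊊ V`), within-`C` arcs
  keep their weights, and arcs into the anchor are boosted by
  `β·d_i` with `d_i = w(C,{i})` the within-`C` in-weight.  These choices
  are pinned down by the cut identity

      cut({s}∪(C∖B), B) = α|B| − g(B) + β·w(C,C)   for every B ∋ t,

  which the test suite verifies exhaustively on small instances.  The
  inclusion-minimal sink side (nodes reaching `t` in the residual graph)
  is the minimal minimizer.  General γ is handled by rescaling α → α/γ;
  α < 0 would need negative source capacities, so those calls route to
  the SFM path.  Self-loop capacity at the anchor is irrelevant to any
  s–t cut and is omitted.

`auto` (the default) picks maxflow when applicable, bruteforce at oracle
scale, mnp beyond it.

**Strength** is computed by discrete-Newton (Dinkelbach) iteration on the
dual ratio: starting from the feasible ratio of a singleton-complement
(which is ≥ σ), each step minimizes the envelope at the current α and
replaces α by the best ratio among the minimizers; iterates decrease
monotonically, stay ≥ σ, and converge in at most |C| steps, finishing
exactly at α = σ(C) where the envelope ties `f_α(C)`.  The certificate
carries the inclusion-minimal argmin family (the complete family is
available from the exhaustive oracle).

**Breakpoints.**  For a fixed anchor, the minimal minimizer is a
right-continuous, strictly nested step function of α with at most
|C|−1 jumps.  The search brackets α with the extreme marginals of `g`
(marginals are monotone in the coalition by supermodularity, so
`min_i g({t,i})−g({t}) − 1` certifies the full set and
`max_i g(C)−g(C∖{i}) + 1` certifies the singleton), then recursively
probes the crossing point of the two bracketing lines: if the minimum at
the crossing equals both lines, that crossing is the single breakpoint
between them; otherwise the probe's minimizer splits the bracket.  Two
solves per breakpoint, all arithmetic exact.

**Divisive recursion.**  `C_α` is computed by repeatedly taking the
minimal-minimizer family `B*_α` on the current ground set (one anchored
solve per node, anchors attaining the global minimum contribute, then
inclusion-minimalization), emitting its non-singleton members, and
recursing on the uncovered remainder — a member of `B*_α` can "dominate"
an equally strong disjoint community, which the next round then finds.
At most |V| rounds.

## Numerics

Every float is an exact rational, so arc weights are held as
`fractions.Fraction` and `g`, envelopes, strengths and breakpoints are
exact by construction; equality and tie decisions never depend on a
tolerance in this regime.  Black-box oracles returning non-rational
values switch the affected comparisons to a 1e-9 absolute tolerance.
Core supports go through `scipy.optimize.linprog` (HiGHS) and are
compared at 1e-7; only optimal values are contractual, not the payoff
vectors (degenerate optima are fine).  Max-flow runs on integer-scaled
capacities via `scipy.sparse.csgraph.maximum_flow` (exact) whenever the
common denominator stays below 2^58, with a float Dinitz fallback
beyond.  Exhaustive oracles refuse ground sets above 12 nodes rather
than run forever.

Envelope subtlety: within a piece's interior the minimal-minimizer
family is constant, and at a breakpoint nested ties collapse onto the
smaller sets; but a set *incomparable* to both adjacent families can be
active at exactly the tie point and then legitimately joins the family
(this occurs on random digraphs and is consistent with the minimizer
lattice).  `PiecewiseCurve` therefore stores interior families per piece
and re-evaluates exactly when queried at a specific α; the engines agree
with this exact semantics.

Determinism: nodes carry a dense first-seen index used for all
orderings; certificates designate the lexicographically smallest witness
under that index; repeated runs are byte-identical.

## Synthetic data

The generators produce the study conditions the framework is analysed
under, not realistic biological networks:

* `example1_graph` — the canonical 3-node instance (worked results above);
* `two_pair_digraph(strong_w=5, weak_w=1)` — two heavy pairs with light
  cross arcs; with β=½, γ=1 the strengths are σ(pair)=7 and σ(V)=13/4,
  so thresholds in between exercise domination and recovery;
* `clique_ring([20,5,20,5])` — the resolution-limit benchmark: rings of
  complete graphs with unit bridges; each K5 (σ=5/2) survives next to
  the K20s because σ(V)=12/5 < 5/2.  On a reduced [5,3,5,3] ring the K3s
  (σ=3/2) fall *below* σ(V)=5/3 and are correctly absorbed — clique
  survival is a threshold fact, not a size fact;
* `random_digraph` / `planted_partition` — seeded generators for
  property tests.  Planted blocks are recovered exactly when their
  strength strictly exceeds that of the enclosing set; with blocks of
  size 5 at p_in=0.9 a single missing edge drops σ(block) to the global
  σ(V), so recovery of every block is not guaranteed instance-by-instance
  (the tests assert the threshold property, which is).

None of these emulate degree heterogeneity, weight noise or missing-data
patterns of real interaction networks; passing tests certify the
algebra and the algorithms, not biological recall.

## Problem sizes and limitations

Exhaustive oracles run to 12 nodes; engine/oracle cross-validation uses
5–8-node random digraphs (20+ seeds) and all bundled fixtures; the
max-flow path is exercised up to the 50-node clique ring, where the full
dendrogram takes about a second.  The implementation favours exactness
and auditability over scale: repeated max-flows instead of a single-run
parametric flow, dense residual bookkeeping, and Fraction arithmetic
put practical limits around 10^3–10^4 nodes for graphical games.  The
dual-form optimization assumes supermodularity; feeding a
non-supermodular oracle voids every guarantee (an empty core is then
possible and is reported as such by the feasibility check).  Overlapping
communities are out of scope — the theory yields laminar families only.
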