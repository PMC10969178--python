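"""Divisive recursion, dendrogram invariants, exports."""

import math
from fractions import Fraction

import pytest

from strongcomm import (
    CharacteristicFunction,
    build_dendrogram,
    communities_at_alpha,
    critical_alphas,
    from_json,
    parse_newick,
    sigma_exact,
    strong_communities_exact,
    to_json,
    to_newick,
)
from strongcomm.fixtures import (
    EDGE_COUNT_PARAMS,
    clique_nodes,
    clique_ring,
    planted_partition,
    block_nodes,
)
from strongcomm.hierarchy import membership_table
from tests.conftest import random_cf


def check_dendrogram_invariants(root, n_nodes):
    """Laminarity, child-sigma monotonicity, internal-node count, leaf set."""
    nodes = list(root.walk())
    sets = [n.members for n in nodes]
    for i, A in enumerate(sets):
        for B in sets[i + 1:]:
            assert A <= B or B <= A or not (A & B), "not laminar"
    internal = [n for n in nodes if not n.is_leaf]
    assert len(internal) <= n_nodes - 1
    leaves = [n for n in nodes if n.is_leaf]
    assert len(leaves) == n_nodes  # exactly the singletons
    assert frozenset().union(*(n.members for n in leaves)) == root.members
    for n in internal:
        covered = set()
        for c in n.children:
            assert c.sigma > n.sigma  # strict increase along any path
            assert c.parent is n
            assert not (covered & c.members)
            covered |= c.members
        assert covered == set(n.members)


def test_recursion_example1(example1_cf):
    cf = example1_cf
    fam = communities_at_alpha(cf, None, Fraction(1, 2))
    assert fam.members == {frozenset("12")}
    assert fam.invocations == 2
    assert communities_at_alpha(cf, None, -1).members == {cf.ground}
    assert communities_at_alpha(cf, None, 1).members == frozenset()


def test_recursion_recovers_dominated_pair(two_pair_cf):
    """At alpha between sigma(V)=13/4 and the pair strengths (7 each), the
    first envelope minimization finds one pair and the recursion must
    recover the other (dominated) pair from the residual ground set."""
    cf = two_pair_cf
    fam = communities_at_alpha(cf, None, 4)
    pairs = {frozenset("12"), frozenset("34")}
    assert fam.members == pairs
    members = sorted(fam.members, key=sorted)
    assert not (members[0] & members[1])
    assert strong_communities_exact(cf, cf.ground, 4) == pairs


def test_dendrogram_example1(example1_cf):
    root = build_dendrogram(example1_cf)
    assert root.members == frozenset("123")
    assert root.sigma == 0
    kids = {k.members: k for k in root.children}
    assert set(kids) == {frozenset("12"), frozenset("3")}
    pair = kids[frozenset("12")]
    assert pair.sigma == 1
    assert {c.members for c in pair.children} == {frozenset("1"), frozenset("2")}
    assert kids[frozenset("3")].sigma == math.inf
    check_dendrogram_invariants(root, 3)


def test_dendrogram_single_edge_path():
    from strongcomm import WeightedDigraph

    g = WeightedDigraph()
    g.add_edge("1", "2", 1)
    cf = CharacteristicFunction.graphical(g, EDGE_COUNT_PARAMS)
    root = build_dendrogram(cf)
    assert root.sigma == 1 and len(root.children) == 2
    assert all(c.is_leaf for c in root.children)


def test_dendrogram_clique_ring_strength_thresholds():
    """Cliques appear as dendrogram nodes exactly when their strength
    (m/2, minus nothing for beta=1) strictly exceeds the strength of the
    enclosing set; on the reduced [5,3,5,3] ring sigma(V)=5/3, so the
    K5s (sigma 5/2) are nodes while the K3s (sigma 3/2) are legitimately
    absorbed -- all cross-checked against the exhaustive strength oracle."""
    sizes = [5, 3, 5, 3]
    g = clique_ring(sizes)
    cf = CharacteristicFunction.graphical(g, EDGE_COUNT_PARAMS)
    root = build_dendrogram(cf)
    assert root.sigma == Fraction(5, 3)
    for k, m in enumerate(sizes):
        B = clique_nodes(sizes, k)
        assert sigma_exact(cf, B).sigma == Fraction(m, 2)
        node = root.find(B)
        if Fraction(m, 2) > root.sigma:
            assert node is not None and node.sigma == Fraction(m, 2)
        else:
            assert node is None
    check_dendrogram_invariants(root, sum(sizes))


def test_dendrogram_matches_exhaustive_union_over_alphas(two_pair_cf):
    """Internal nodes == union of C_alpha over all alpha (oracle sweep)."""
    cf = two_pair_cf
    root = build_dendrogram(cf)
    sweep = set()
    crits = critical_alphas(cf)
    probes = [crits[0] - 1] + crits + \
        [(a + b) / 2 for a, b in zip(crits, crits[1:])]
    for a in probes:
        sweep |= set(strong_communities_exact(cf, cf.ground, a))
    assert {n.members for n in root.internal_nodes()} == sweep
    for n in root.internal_nodes():
        assert n.sigma == sigma_exact(cf, n.members).sigma


@pytest.mark.parametrize("seed", range(5))
def test_recursion_equals_oracle_on_random_digraphs(seed):
    cf = random_cf(6, seed, beta=[0, Fraction(1, 2), 1][seed % 3])
    V = cf.ground
    crits = critical_alphas(cf)
    probes = [crits[0] - 1] + crits + \
        [(a + b) / 2 for a, b in zip(crits, crits[1:])] + [crits[-1] + 1]
    for a in probes:
        fam = communities_at_alpha(cf, None, a)
        assert fam.members == strong_communities_exact(cf, V, a), f"alpha={a}"
        assert fam.invocations <= len(V) + 1
        members = sorted(fam.members, key=sorted)
        for i, A in enumerate(members):
            for B in members[i + 1:]:
                assert not (A & B)


@pytest.mark.parametrize("seed", range(5))
def test_hierarchy_nesting_across_thresholds(seed):
    """Members at a higher threshold nest inside (or avoid) lower-threshold ones."""
    cf = random_cf(6, seed + 5)
    crits = critical_alphas(cf)
    probes = [crits[0] - 1] + crits + [crits[-1] + 1]
    fams = [communities_at_alpha(cf, None, a).members for a in probes]
    for i in range(len(probes)):
        for j in range(i + 1, len(probes)):
            for C2 in fams[j]:
                assert any(C2 <= C1 for C1 in fams[i]) or \
                    all(not (C2 & C1) for C1 in fams[i])


@pytest.mark.parametrize("seed", range(4))
def test_dendrogram_invariants_random(seed):
    cf = random_cf(7, seed + 20)
    root = build_dendrogram(cf)
    check_dendrogram_invariants(root, 7)
    crits = set(critical_alphas(cf))
    for n in root.internal_nodes():
        if n.members != cf.ground:
            assert n.sigma in crits
        assert n.sigma == sigma_exact(cf, n.members).sigma


def test_screening_property_members_absorb_or_avoid_strong_sets():
    """Any set stronger than alpha is inside a B*-member or disjoint from all."""
    from strongcomm import b_star
    from strongcomm.game import subsets

    cf = random_cf(6, seed=11)
    V = cf.ground
    for a in [0, 1, 2]:
        fam = b_star(cf, V, a)
        for C in subsets(sorted(V), 2, 6):
            if sigma_exact(cf, C).sigma > a:
                for B in fam:
                    assert C <= B or not (C & B)


def test_critical_alphas_example1(example1_cf):
    # union of per-anchor breakpoints: anchors 1,2 give {0,1}, anchor 3
    # hands over from V to {3} at 1/2 (line 3a-1 crosses a there)
    assert critical_alphas(example1_cf) == [0, Fraction(1, 2), 1]


def test_critical_alphas_edgeless():
    from strongcomm import WeightedDigraph

    g = WeightedDigraph(nodes="abcd")
    cf = CharacteristicFunction.graphical(g, EDGE_COUNT_PARAMS)
    assert critical_alphas(cf) == [0]


def test_planted_partition_blocks(example1_cf):
    """Blocks strictly stronger than sigma(V) are dendrogram nodes and no
    non-root community mixes blocks."""
    k, size = 3, 5
    g = planted_partition(k, size, 0.9, 0.05, 1, 1, seed=1)
    cf = CharacteristicFunction.graphical(g, EDGE_COUNT_PARAMS)
    root = build_dendrogram(cf)
    sV = root.sigma
    blocks = [block_nodes(k, size, b) for b in range(k)]
    for B in blocks:
        if sigma_exact(cf, B).sigma > sV:
            assert root.find(B) is not None
    for n in root.internal_nodes():
        if n.members == cf.ground:
            continue
        assert any(n.members <= B for B in blocks), "community mixes blocks"
    check_dendrogram_invariants(root, k * size)


# -- serialization -----------------------------------------------------

def test_newick_example1(example1_cf):
    root = build_dendrogram(example1_cf)
    nwk = to_newick(root)
    assert nwk.count("[&sigma=") == 2
    assert "[&sigma=0]" in nwk and "[&sigma=1]" in nwk
    back = parse_newick(nwk)
    assert back == root


def test_newick_single_leaf():
    from strongcomm import WeightedDigraph

    g = WeightedDigraph(nodes=["1"])
    cf = CharacteristicFunction.graphical(g, EDGE_COUNT_PARAMS)
    root = build_dendrogram(cf)
    assert to_newick(root) == "1;"
    assert parse_newick("1;") == root


@pytest.mark.parametrize("seed", range(5))
def test_serialization_round_trips(seed):
    cf = random_cf(6, seed + 30)
    root = build_dendrogram(cf)
    assert parse_newick(to_newick(root)) == root
    assert from_json(to_json(root)) == root


def test_newick_quotes_awkward_labels():
    from strongcomm import WeightedDigraph

    g = WeightedDigraph()
    g.add_edge("a b", "c,d", 1)
    cf = CharacteristicFunction.graphical(g, EDGE_COUNT_PARAMS)
    root = build_dendrogram(cf)
    assert parse_newick(to_newick(root)) == root


def test_membership_table(two_pair_cf):
    fam = communities_at_alpha(two_pair_cf, None, 4)
    table = membership_table(fam)
    lines = table.strip().splitlines()
    assert lines[0] == "node\tcommunity\tsigma"
    assert len(lines) == 5  # header + 4 nodes
    ids = {line.split("\t")[0]: line.split("\t")[1] for line in lines[1:]}
    assert ids["1"] == ids["2"] and ids["3"] == ids["4"]
    assert ids["1"] != ids["3"]
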