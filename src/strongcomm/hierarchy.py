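"""Strong-community families and the strength dendrogram.

``communities_at_alpha`` implements the divisive recursion: compute the
minimal-minimizer family B*_alpha on the current ground set, emit its
non-singleton members (they are strong communities), strip all covered
nodes and recurse on the remainder -- at most |V| rounds.  A member of
B*_alpha can shadow ("dominate") another strong community, which is
exactly why the recursion re-runs on the residual ground set.

The dendrogram stacks these families over every threshold: each internal
node C carries sigma(C), its children are the strong communities of C at
threshold sigma(C) plus a leaf for every uncovered node, leaves are the
singletons (annotated +inf).  The node sets form a laminar family with
strictly increasing sigma along any root-to-leaf path and at most
|V| - 1 internal nodes.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction

from .game import CharacteristicFunction
from .graph import as_fraction
from .sfm import b_star, sigma as _sigma

__all__ = ["CommunityFamily", "DendrogramNode", "communities_at_alpha",
           "build_dendrogram", "critical_alphas", "to_newick", "to_json",
           "parse_newick", "from_json", "membership_table"]


@dataclass(frozen=True)
class CommunityFamily:
    """C_alpha on a ground set: disjoint maximal sets with sigma > alpha."""

    alpha: object
    members: frozenset  # of frozensets, each of size >= 2
    invocations: int  # recursive rounds used, terminating round included
    engine: str = "auto"

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)


def communities_at_alpha(cf: CharacteristicFunction, V=None, alpha=0,
                         engine: str = "auto") -> CommunityFamily:
    """All strong communities within V at threshold alpha (strict)."""
    ground = frozenset(str(v) for v in (cf.ground if V is None else V))
    alpha = as_fraction(alpha)
    members: list[frozenset] = []
    rounds = 0
    while True:
        rounds += 1
        if len(ground) <= 1:
            break
        fam = b_star(cf, ground, alpha, engine)
        members.extend(B for B in fam if len(B) >= 2)
        covered = frozenset().union(*fam)
        ground = ground - covered
    return CommunityFamily(alpha=alpha, members=frozenset(members),
                           invocations=rounds, engine=engine)


@dataclass
class DendrogramNode:
    """A node of the strength dendrogram (internal community or leaf)."""

    members: frozenset
    sigma: object  # Fraction/float for internal nodes, math.inf for leaves
    children: tuple = ()
    parent: "DendrogramNode | None" = field(default=None, repr=False,
                                            compare=False)

    @property
    def is_leaf(self) -> bool:
        return len(self.members) == 1

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def internal_nodes(self):
        return [n for n in self.walk() if not n.is_leaf]

    def leaves(self):
        return [n for n in self.walk() if n.is_leaf]

    def find(self, S) -> "DendrogramNode | None":
        S = frozenset(str(v) for v in S)
        for n in self.walk():
            if n.members == S:
                return n
        return None

    def parent_of(self, S) -> "DendrogramNode | None":
        node = self.find(S)
        return None if node is None else node.parent


def build_dendrogram(cf: CharacteristicFunction, V=None,
                     engine: str = "auto") -> DendrogramNode:
    """Top-down dendrogram: the union of C_alpha over every threshold."""
    ground = frozenset(str(v) for v in (cf.ground if V is None else V))
    if not ground:
        raise ValueError("empty ground set")
    key = cf.sort_key()

    def build(C: frozenset) -> DendrogramNode:
        if len(C) == 1:
            return DendrogramNode(members=C, sigma=math.inf)
        s = _sigma(cf, C, engine)
        fam = communities_at_alpha(cf, C, s.sigma, engine).members
        covered = frozenset().union(*fam) if fam else frozenset()
        kids = [build(B) for B in sorted(fam, key=lambda B: min(key(v) for v in B))]
        kids += [DendrogramNode(members=frozenset({v}), sigma=math.inf)
                 for v in sorted(C - covered, key=key)]
        node = DendrogramNode(members=C, sigma=s.sigma, children=tuple(kids))
        for k in node.children:
            k.parent = node
        return node

    return build(ground)


def critical_alphas(cf: CharacteristicFunction, V=None,
                    engine: str = "auto") -> list:
    """Sorted union of every anchor's breakpoints.

    Evaluating C_alpha at these thresholds (and only these) is enough to
    recover every strong community; in particular every sigma annotation
    of the dendrogram appears in this list.
    """
    from .sfm import breakpoints_for_t

    ground = frozenset(str(v) for v in (cf.ground if V is None else V))
    crits: set = set()
    for t in sorted(ground, key=cf.sort_key()):
        crits.update(breakpoints_for_t(cf, ground, t, engine).breakpoints)
    return sorted(crits)


# ----------------------------------------------------------------------
# Serialization
# ----------------------------------------------------------------------

_NEEDS_QUOTE = re.compile(r"[\s(),;:\[\]']")


def _newick_label(v: str) -> str:
    if _NEEDS_QUOTE.search(v):
        return "'" + v.replace("'", "''") + "'"
    return v


def _sigma_str(s) -> str:
    if isinstance(s, Fraction):
        return str(s)  # "1" or "5/2": parses back exactly
    return repr(float(s))


def to_newick(root: DendrogramNode) -> str:
    """Newick export; internal labels carry sigma as a [&sigma=...] comment."""

    def render(n: DendrogramNode) -> str:
        if n.is_leaf:
            return _newick_label(next(iter(n.members)))
        inner = ",".join(render(c) for c in n.children)
        return f"({inner})[&sigma={_sigma_str(n.sigma)}]"

    return render(root) + ";"


def parse_newick(text: str) -> DendrogramNode:
    """Parse the Newick dialect produced by :func:`to_newick`."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_node() -> DendrogramNode:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            kids = [parse_node()]
            while s[pos] == ",":
                pos += 1
                kids.append(parse_node())
            if s[pos] != ")":
                raise ValueError(f"expected ')' at position {pos}")
            pos += 1
            m = re.match(r"\[&sigma=([^\]]+)\]", s[pos:])
            if not m:
                raise ValueError(f"missing sigma annotation at position {pos}")
            pos += m.end()
            sig = as_fraction(m.group(1))
            members = frozenset().union(*(k.members for k in kids))
            node = DendrogramNode(members=members, sigma=sig,
                                  children=tuple(kids))
            for k in kids:
                k.parent = node
            return node
        # leaf label (possibly quoted)
        if s[pos] == "'":
            m = re.match(r"'((?:[^']|'')*)'", s[pos:])
            label = m.group(1).replace("''", "'")
            pos += m.end()
        else:
            m = re.match(r"[^(),;\[\]]+", s[pos:])
            if not m:
                raise ValueError(f"expected leaf label at position {pos}")
            label = m.group(0)
            pos += m.end()
        return DendrogramNode(members=frozenset({label}), sigma=math.inf)

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters after position {pos}")
    return root


def _sigma_json(s):
    if s == math.inf:
        return "inf"
    f = float(s)
    if isinstance(s, Fraction) and Fraction(f) != s:
        return str(s)  # exact fraction fallback for non-dyadic values
    return f


def to_json(root: DendrogramNode, indent=None) -> str:
    def as_dict(n: DendrogramNode) -> dict:
        return {
            "set": sorted(n.members),
            "sigma": _sigma_json(n.sigma),
            "children": [as_dict(c) for c in n.children],
        }

    return json.dumps(as_dict(root), indent=indent)


def from_json(text: str) -> DendrogramNode:
    def build(d: dict) -> DendrogramNode:
        sig = d["sigma"]
        sig = math.inf if sig == "inf" else as_fraction(sig)
        kids = tuple(build(c) for c in d["children"])
        node = DendrogramNode(members=frozenset(d["set"]), sigma=sig,
                              children=kids)
        for k in kids:
            k.parent = node
        return node

    return build(json.loads(text))


def membership_table(family: CommunityFamily,
                     sigmas: dict | None = None) -> str:
    """Flat TSV: ``node<TAB>community_id<TAB>sigma`` for one threshold."""
    lines = ["node\tcommunity\tsigma"]
    for cid, B in enumerate(sorted(family.members, key=sorted)):
        s = sigmas.get(B, "") if sigmas else ""
        for v in sorted(B):
            lines.append(f"{v}\t{cid}\t{s}")
    return "\n".join(lines) + "\n"
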