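"""Synthetic glycans and a brute-force matching oracle.

The generator draws random, structurally valid glycan trees (seeded,
bit-reproducible) to stand in for real glycomes in property-based tests.
The oracle, :func:`brute_force_match`, computes pattern matches by direct
definition — enumerate every connected subtree of the glycan, expand the
pattern's quantifiers into every concrete repeat-count realization, and
search for a structure-preserving bijection between the two — sharing
nothing with the engine's constructive path tracing beyond the parsers
and the AST label/linkage compatibility predicates.  Agreement between
the two is what the acceptance suite certifies.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

from .glycan_io import GlycanGraph, LinkageLabel, parse_iupac
from .pattern import (
    DEFAULT_C2_PREFIXES,
    PatternElement,
    Quantifier,
    linkage_matches,
    parse_pattern,
)

__all__ = [
    "SyntheticGlycanSpec",
    "generate_glycan",
    "generate_corpus",
    "brute_force_match",
    "FEATURES",
    "feature_pattern",
    "pattern_corpus",
]


# --------------------------------------------------------------------------
# synthetic glycan generation
# --------------------------------------------------------------------------

DEFAULT_ALPHABET = (
    "Gal", "Glc", "Man", "GlcNAc", "GalNAc", "Fuc", "Neu5Ac", "Neu5Gc", "Xyl",
)

#: (anomer, acceptor carbon) pool; the donor carbon is set by the child
#: residue (C2 for ulosonic acids, C1 otherwise)
DEFAULT_LINKAGE_POOL = (
    ("a", 2), ("a", 3), ("a", 4), ("a", 6),
    ("b", 2), ("b", 3), ("b", 4), ("b", 6),
)


@dataclass(frozen=True)
class SyntheticGlycanSpec:
    """Parameters of the random glycan generator.

    ``branch_prob`` is the per-attachment probability (from the third
    residue on) of starting a side branch at an existing branch point
    instead of extending the current chain tip; ``unknown_linkage_prob``
    replaces a drawn linkage with the unknown form (``?1-?``/``?2-?``).
    The same spec and seed always produce the identical string.
    """

    alphabet: tuple = DEFAULT_ALPHABET
    linkage_pool: tuple = DEFAULT_LINKAGE_POOL
    max_residues: int = 10
    branch_prob: float = 0.25
    unknown_linkage_prob: float = 0.05
    seed: int = 0


def _is_c2(token: str) -> bool:
    return token.startswith(DEFAULT_C2_PREFIXES)


def generate_glycan(spec: SyntheticGlycanSpec) -> str:
    """Draw one random IUPAC-condensed glycan string.

    The result always parses and satisfies every :class:`GlycanGraph`
    invariant; C2-linking residues (sialic acids etc.) are only emitted
    with C2 donor carbons.
    """
    if spec.max_residues < 1:
        raise ValueError("max_residues must be >= 1")
    rng = random.Random(spec.seed)
    n = rng.randint(1, spec.max_residues)
    tokens = [rng.choice(spec.alphabet)]
    children: list[list] = [[]]          # node -> [(child, LinkageLabel)]
    tip = 0
    branch_points: set[int] = set()      # nodes that already have a child

    for k in range(1, n):
        if k == 1:
            target = 0
        elif branch_points and rng.random() < spec.branch_prob:
            target = rng.choice(sorted(branch_points))
        else:
            target = tip
        token = rng.choice(spec.alphabet)
        donor = 2 if _is_c2(token) else 1
        if rng.random() < spec.unknown_linkage_prob:
            link = LinkageLabel("?", donor, None)
        else:
            used = {l.carbon_to for _, l in children[target]}
            anomer, cto = rng.choice(spec.linkage_pool)
            for _ in range(8):           # avoid acceptor-carbon collisions
                if cto not in used:
                    break
                anomer, cto = rng.choice(spec.linkage_pool)
            link = LinkageLabel(anomer, donor, cto)
        new = len(tokens)
        tokens.append(token)
        children[target].append((new, link))
        children.append([])
        branch_points.add(target)
        tip = new

    def serialize(v: int) -> str:
        kids = children[v]
        if not kids:
            return tokens[v]
        parts = [serialize(c) + str(l) for c, l in kids]
        return parts[0] + "".join(f"({p})" for p in parts[1:]) + tokens[v]

    return serialize(0)


def generate_corpus(spec: SyntheticGlycanSpec, n: int) -> list:
    """``n`` independent draws, seeded as ``spec.seed + 7919*i``."""
    return [generate_glycan(replace(spec, seed=spec.seed + 7919 * i))
            for i in range(n)]


# --------------------------------------------------------------------------
# brute-force oracle
# --------------------------------------------------------------------------

class _Slot:
    """One node of a concrete (quantifier-free) pattern tree."""

    __slots__ = ("kind", "spec", "region", "children")

    def __init__(self, kind, spec, region, children):
        self.kind = kind          # 'res' | 'link'
        self.spec = spec          # LabelSpec (res) or linkage spec set/None
        self.region = region      # 'main' | 'behind' | 'ahead'
        self.children = children  # list of _Slot (leafward)

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)


class _CRes:
    """Concrete chain element: a residue spec, its rootward linkage spec,
    and fully concretized branch chains."""

    __slots__ = ("spec", "link", "branches", "region")

    def __init__(self, spec, link, branches, region):
        self.spec = spec
        self.link = link
        self.branches = branches
        self.region = region


def _counts(q: Quantifier, ceiling: int) -> range:
    hi = ceiling if q.max_count is None else min(q.max_count, ceiling)
    return range(q.min_count, hi + 1)


def _conc_chain(elements: Sequence[PatternElement], region: str,
                budget: int) -> Iterator[tuple]:
    """Yield ``(chain, residue_cost)`` for every concrete realization."""
    if budget < 0:
        return
    if not elements:
        yield [], 0
        return
    el = elements[0]
    if el.kind == "group" and el.lookaround == "none" and el.quantifier.is_default:
        # consecutive branch groups bind to the next residue element
        k = 0
        groups = []
        while (k < len(elements) and elements[k].kind == "group"
               and elements[k].lookaround == "none"
               and elements[k].quantifier.is_default):
            groups.append(elements[k])
            k += 1
        if (k >= len(elements) or elements[k].kind != "residue"
                or not elements[k].quantifier.is_default):
            raise ValueError("branch group must precede an unquantified residue")
        res_el = elements[k]
        options = [list(_conc_chain(gr.children[0], region, budget - 1))
                   for gr in groups]
        for combo in itertools.product(*options):
            bchains = tuple(c for c, _ in combo if c)
            bcost = sum(cost for _, cost in combo)
            base = _CRes(res_el.spec, res_el.spec.linkage, bchains, region)
            for rest, rcost in _conc_chain(elements[k + 1:], region,
                                           budget - 1 - bcost):
                yield [base] + rest, 1 + bcost + rcost
        return
    if el.kind == "residue":
        unit = _CRes(el.spec, el.spec.linkage, (), region)
        for c in _counts(el.quantifier, budget):
            for rest, rcost in _conc_chain(elements[1:], region, budget - c):
                yield [unit] * c + rest, c + rcost
        return
    # quantified group: c independent concretizations of the body
    for c in _counts(el.quantifier, budget):

        def reps(i: int, remaining: int) -> Iterator[tuple]:
            if i == c:
                yield [], 0
                return
            for uchain, ucost in _conc_chain(el.children[0], region, remaining):
                for tail, tcost in reps(i + 1, remaining - ucost):
                    yield uchain + tail, ucost + tcost

        for body, bcost in reps(0, budget):
            for rest, rcost in _conc_chain(elements[1:], region, budget - bcost):
                yield body + rest, bcost + rcost


def _chain_to_slots(chain: Sequence[_CRes]) -> _Slot:
    def build(ch, i):
        cres = ch[i]
        slot = _Slot("res", cres.spec, cres.region, [])
        if i > 0:
            prev = ch[i - 1]
            slot.children.append(
                _Slot("link", prev.link, prev.region, [build(ch, i - 1)]))
        for b in cres.branches:
            btop = build(b, len(b) - 1)
            slot.children.append(
                _Slot("link", b[-1].link, b[-1].region, [btop]))
        return slot

    top = build(chain, len(chain) - 1)
    if chain[-1].link is not None:
        top = _Slot("link", chain[-1].link, chain[-1].region, [top])
    return top


def _connected_subtrees(g: GlycanGraph) -> dict:
    """All connected node subsets, grouped by size.

    Children in the canonical indexing always precede their parent, so a
    single increasing sweep visits every child before its parent.
    """
    per_top: dict[int, list] = {}
    for v in range(g.n_nodes):
        options = [[None] + per_top[c] for c in g.children(v)]
        subs = []
        for combo in itertools.product(*options):
            s = frozenset({v}).union(*(x for x in combo if x is not None))
            subs.append(s)
        per_top[v] = subs
    by_size: dict[int, list] = {}
    for v, subs in per_top.items():
        for s in subs:
            by_size.setdefault(len(s), []).append((v, s))
    return by_size


def _assign(slot: _Slot, node: int, g: GlycanGraph,
            tset: frozenset) -> Iterator[frozenset]:
    """Yield the lookaround node set of every bijection rooted here."""
    if slot.kind == "link":
        if not g.is_linkage(node):
            return
        if slot.spec is not None and not linkage_matches(slot.spec, g.labels[node]):
            return
    else:
        if g.is_linkage(node):
            return
        if not slot.spec.matches_token(g.labels[node]):
            return
    tkids = [c for c in g.children(node) if c in tset]
    if len(tkids) != len(slot.children):
        return
    self_look = frozenset() if slot.region == "main" else frozenset({node})
    if not slot.children:
        yield self_look
        return
    for perm in itertools.permutations(tkids):
        child_sets = []
        ok = True
        for cslot, cnode in zip(slot.children, perm):
            found = list(_assign(cslot, cnode, g, tset))
            if not found:
                ok = False
                break
            child_sets.append(found)
        if not ok:
            continue
        for combo in itertools.product(*child_sets):
            yield self_look.union(*combo)


def brute_force_match(pattern: str, glycan: str, policy: str = "greedy",
                      max_residues: int = 12) -> list:
    """Ground-truth pattern matching by exhaustive enumeration.

    Only feasible for small glycans (``max_residues`` cap, default 12);
    output format and ordering match
    :func:`glyre.engine.trace_match`.
    """
    g = parse_iupac(glycan)
    if g.n_residues > max_residues:
        raise ValueError(
            f"glycan has {g.n_residues} residues; oracle cap is {max_residues}")
    ast = parse_pattern(pattern)
    budget = g.n_residues
    behind = [e for e in ast.elements if e.lookaround == "behind"]
    main = [e for e in ast.elements if e.lookaround == "none"]
    ahead = [e for e in ast.elements if e.lookaround == "ahead"]

    def chains_of(els, region):
        if not els:
            return [([], 0)]
        return list(_conc_chain(els, region, budget))

    behind_chains = chains_of(behind[0].children[0] if behind else [], "behind")
    main_chains = chains_of(main, "main")
    ahead_chains = chains_of(ahead[0].children[0] if ahead else [], "ahead")

    by_size = _connected_subtrees(g)
    mains: set[frozenset] = set()
    for (bc, bcost), (mc, mcost), (ac, acost) in itertools.product(
            behind_chains, main_chains, ahead_chains):
        chain = bc + mc + ac
        if not chain or bcost + mcost + acost > budget:
            continue
        top = _chain_to_slots(chain)
        n_slots = top.size()
        for tnode, tset in by_size.get(n_slots, ()):
            for look in _assign(top, tnode, g, tset):
                mains.add(tset - look)

    mains.discard(frozenset())
    if policy == "greedy":
        kept = [m for m in mains if not any(m < o for o in mains)]
    elif policy == "lazy":
        kept = [m for m in mains if not any(o < m for o in mains)]
    elif policy == "all":
        kept = list(mains)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    kept.sort(key=lambda m: (min(m), -len(m), tuple(sorted(m))))
    return [sorted(m) for m in kept]


# --------------------------------------------------------------------------
# feature-directed pattern corpus
# --------------------------------------------------------------------------

FEATURES = (
    "plain", "wildcard", "linkage_alternation", "negation",
    "optional", "star", "plus", "exact_count", "range_count", "min_count",
    "lazy", "branch_group", "lookahead", "lookbehind",
)


def _shorthand(g: GlycanGraph, r: int) -> str:
    """Pattern text for the linkage from residue ``r`` toward the root."""
    link, _ = g.residue_parent(r)
    lab = g.labels[link]
    token = g.labels[r]
    donor = 2 if token.startswith(DEFAULT_C2_PREFIXES) else 1
    if (lab.anomer != "?" and lab.carbon_to is not None
            and not lab.alternatives and lab.carbon_from == donor):
        return f"{lab.anomer}{lab.carbon_to}"
    return str(lab)


def _random_chain(g: GlycanGraph, rng: random.Random, max_len: int = 4) -> list:
    head = rng.choice(g.residues)
    chain = [head]
    while len(chain) < max_len:
        kids = g.residue_children(chain[-1])
        if not kids or rng.random() < 0.3:
            break
        _, child = rng.choice(kids)
        chain.append(child)
    chain.reverse()  # leafward -> rootward
    return chain


def feature_pattern(glycan: str, feature: str, rng: random.Random) -> str:
    """Derive a pattern exercising one grammar feature from a glycan.

    Patterns are built from randomly chosen substructures of the glycan so
    that matches occur often, then mutated to use the requested feature
    (sometimes in a deliberately non-matching way).
    """
    g = parse_iupac(glycan)
    chain = _random_chain(g, rng)
    toks = [g.labels[r] for r in chain]
    links = [_shorthand(g, r) for r in chain[:-1]] + [""]
    quants = [""] * len(chain)
    n = len(chain)
    i = rng.randrange(n)

    if feature == "wildcard":
        toks[i] = rng.choice((".", "Monosaccharide"))
    elif feature == "linkage_alternation":
        done = False
        for j in list(range(n - 1)):
            if len(links[j]) == 2 and links[j][1].isdigit():
                other = (int(links[j][1]) % 9) + 1
                links[j] = f"{links[j]}/{other}"
                done = True
                break
        if not done:
            links[-1] = "b3/4"  # dangling-linkage requirement on the last residue
    elif feature == "negation":
        if rng.random() < 0.5:
            toks[i] = "!" + toks[i]          # positional mismatch: no match here
        else:
            others = [t for t in DEFAULT_ALPHABET if t != toks[i]]
            toks[i] = "!" + rng.choice(others)
    elif feature == "optional":
        quants[i] = "?"
    elif feature == "star":
        if rng.random() < 0.5:
            toks[i] = "."
        quants[i] = "*"
    elif feature == "plus":
        if rng.random() < 0.5:
            toks[i] = "."
        quants[i] = "+"
    elif feature == "exact_count":
        quants[i] = "{%d}" % rng.choice((1, 2))
    elif feature == "range_count":
        quants[i] = rng.choice(("{0,2}", "{1,2}", "{1,3}"))
    elif feature == "min_count":
        quants[i] = rng.choice(("{1,}", "{2,}"))
    elif feature == "lazy":
        quants[i] = rng.choice(("??", "+?", "*?", "{1,2}?"))
        if quants[i] in ("+?", "*?") and rng.random() < 0.5:
            toks[i] = "."
    elif feature == "branch_group":
        for r in g.residues:
            kids = g.residue_children(r)
            if len(kids) >= 2:
                (l1, c1), (l2, c2) = kids[0], kids[1]
                return (f"{g.labels[c2]}{_shorthand(g, c2)}"
                        f"({g.labels[c1]}{_shorthand(g, c1)})"
                        f"{g.labels[r]}")
        t1, t2 = rng.choice(DEFAULT_ALPHABET), rng.choice(DEFAULT_ALPHABET)
        return f"({t1}a3){t2}"
    elif feature == "lookbehind":
        if n >= 2:
            behind = f"{toks[0]}{links[0]}"
            body = "".join(t + l + q for t, l, q in
                           zip(toks[1:], links[1:], quants[1:]))
            return f"(?<={behind}){body}"
        return f"(?<=.){toks[0]}"
    elif feature == "lookahead":
        if n >= 2:
            body = "".join(t + l + q for t, l, q in
                           zip(toks[:-1], links[:-1], quants[:-1]))
            return f"{body}(?={toks[-1]})"
        return f".(?={toks[0]})"
    elif feature != "plain":
        raise ValueError(f"unknown feature {feature!r}")

    return "".join(t + l + q for t, l, q in zip(toks, links, quants))


def pattern_corpus(feature: str, glycans: Sequence[str],
                   rng: random.Random) -> list:
    """``(pattern, glycan)`` pairs exercising one feature across a corpus."""
    return [(feature_pattern(gl, feature, rng), gl) for gl in glycans]
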