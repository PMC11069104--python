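"""Match glyco-regex patterns against glycan graphs.

The engine compiles a :class:`~glyre.pattern.PatternAST` into a linear
program of residue and repeat items (branches bound to the residue they
hang from, lookaround regions tagged), then traces every way the program
can embed into the glycan tree: each pattern chain element must match a
residue that is the child — via a linkage satisfying the element's linkage
spec — of the residue matched by the next element.  A match is therefore
always a connected portion of the glycan graph, including the linkage
nodes between stitched elements.  Quantified items expand into allowed
repeat counts; lookahead/lookbehind nodes are required to be present but
are excluded from reported matches; the greedy policy (default) reports
count-maximal matches, the lazy policy count-minimal ones.

Matching is performed on the graph, never on the string, so results are
insensitive to how branches happen to be ordered in a particular glycan
string.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .glycan_io import (
    GlycanGraph,
    GlycanParseError,
    GlyreError,
    parse_iupac,
    to_string,
)
from .pattern import (
    CountConstraint,
    LabelSpec,
    PatternAST,
    PatternElement,
    PatternParseError,
    linkage_matches,
    parse_pattern,
)

__all__ = [
    "SegmentMatch",
    "MatchResult",
    "segment_matches",
    "check_counts",
    "trace_match",
    "get_match",
]


# --------------------------------------------------------------------------
# result types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentMatch:
    """One embedding of a plain pattern segment into the glycan.

    ``attachment`` holds the residues available for stitching with the
    neighboring segments: ``(leafward_node, rootward_node)``.
    """

    segment_id: int
    node_set: frozenset
    attachment: tuple


@dataclass(frozen=True)
class MatchResult:
    """All matches of one pattern on one glycan.

    ``matches`` are sorted node-index lists (canonical indices of
    ``glycan``); ``match_strings`` the corresponding serialized
    sub-glycans.  An empty ``matches`` list means no match (not an error).
    """

    glycan: str
    matches: tuple
    match_strings: tuple


# --------------------------------------------------------------------------
# compilation: AST -> item program
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _ResidueItem:
    spec: LabelSpec
    branches: tuple          # tuple of item tuples, each a chain program
    region: str              # 'main' | 'behind' | 'ahead'

    @property
    def linkage(self):
        return self.spec.linkage


@dataclass(frozen=True)
class _RepeatItem:
    unit: tuple              # item chain repeated count times
    min_count: int
    max_count: int | None    # None = unbounded (ceiling at match time)
    lazy: bool
    region: str


def _compile_elements(elements: Sequence[PatternElement], region: str) -> tuple:
    items: list = []
    pending: list[tuple] = []
    for el in elements:
        if el.kind == "group" and el.lookaround == "none" and el.quantifier.is_default:
            pending.append(_compile_elements(el.children[0], region))
            continue
        if pending and not (el.kind == "residue" and el.quantifier.is_default):
            raise PatternParseError(
                "a branch group must be followed by an unquantified residue")
        if el.kind == "residue":
            item = _ResidueItem(el.spec, tuple(pending), region)
            pending = []
            if el.quantifier.is_default:
                items.append(item)
            else:
                items.append(_RepeatItem((item,), el.quantifier.min_count,
                                         el.quantifier.max_count,
                                         el.quantifier.lazy, region))
        else:  # quantified group: a repeat unit along the chain
            unit = _compile_elements(el.children[0], region)
            items.append(_RepeatItem(unit, el.quantifier.min_count,
                                     el.quantifier.max_count,
                                     el.quantifier.lazy, region))
    if pending:
        raise PatternParseError("a branch group must be followed by a residue")
    return tuple(items)


def _compile(ast: PatternAST) -> tuple:
    behind = [e for e in ast.elements if e.lookaround == "behind"]
    main = [e for e in ast.elements if e.lookaround == "none"]
    ahead = [e for e in ast.elements if e.lookaround == "ahead"]
    items: list = []
    for el in behind:
        items.extend(_compile_elements(el.children[0], "behind"))
    items.extend(_compile_elements(main, "main"))
    for el in ahead:
        items.extend(_compile_elements(el.children[0], "ahead"))
    return tuple(items)


# --------------------------------------------------------------------------
# the embedder: anchored recursive path tracing
# --------------------------------------------------------------------------

def _residue_token(g: GlycanGraph, r: int) -> str:
    return g.labels[r]


def _embed(g: GlycanGraph, items: tuple, attach_to: int | None,
           pin_root: int | None = None) -> Iterator[tuple]:
    """Enumerate embeddings of an item chain into the glycan.

    ``items`` run leafward -> rootward; the chain's rootward-most realized
    residue must attach as a child of residue ``attach_to`` (``None`` =
    free end).  Yields ``(assignment, leaf_residue)`` where ``assignment``
    maps matched node index -> region and ``leaf_residue`` is the residue
    matched by the leafward-most realized item (``None`` for an empty
    realization).  ``pin_root`` restricts the rootward-most residue of a
    free-ended chain (used by :func:`segment_matches`).
    """
    if not items:
        yield {}, None
        return
    it = items[-1]
    rest = items[:-1]

    if isinstance(it, _RepeatItem):
        ceiling = g.n_residues if it.max_count is None else min(it.max_count, g.n_residues)
        for c in range(it.min_count, ceiling + 1):
            expanded = rest + it.unit * c
            if not expanded:
                yield {}, None
                continue
            yield from _embed(g, expanded, attach_to, pin_root)
        return

    # residue item: collect candidate (residue, base assignment) pairs
    candidates = []
    if attach_to is None:
        for r in g.residues:
            if pin_root is not None and r != pin_root:
                continue
            base = {r: it.region}
            if it.linkage is not None:
                up = g.residue_parent(r)
                if up is None:
                    continue
                link, _ = up
                if not linkage_matches(it.linkage, g.labels[link]):
                    continue
                base[link] = it.region  # dangling rootward linkage, included
            candidates.append((r, base))
    else:
        for link, child in g.residue_children(attach_to):
            if not linkage_matches(it.linkage, g.labels[link]):
                continue
            candidates.append((child, {child: it.region, link: it.region}))

    for r, base in candidates:
        if not it.spec.matches_token(_residue_token(g, r)):
            continue
        partials = [base]
        for branch in it.branches:
            grown = []
            for asg in partials:
                for basg, _ in _embed(g, branch, attach_to=r):
                    if not basg:
                        # branch realized empty (all-optional content)
                        grown.append(dict(asg))
                    elif not (asg.keys() & basg.keys()):
                        merged = dict(asg)
                        merged.update(basg)
                        grown.append(merged)
            partials = grown
            if not partials:
                break
        for asg in partials:
            for casg, leaf in _embed(g, rest, attach_to=r):
                if casg.keys() & asg.keys():
                    continue
                merged = dict(asg)
                merged.update(casg)
                yield merged, (leaf if leaf is not None else r)


def _all_assignments(g: GlycanGraph, ast: PatternAST) -> dict:
    """Every valid full match: map main-region node set -> lookaround node set."""
    prog = _compile(ast)
    out: dict = {}
    for asg, _ in _embed(g, prog, None):
        main = frozenset(n for n, reg in asg.items() if reg == "main")
        look = frozenset(n for n, reg in asg.items() if reg != "main")
        out.setdefault(main, look)
    return out


def _apply_policy(mains: Iterable[frozenset], policy: str) -> list:
    sets = [m for m in mains if m]
    if policy == "greedy":
        return [m for m in sets if not any(m < o for o in sets)]
    if policy == "lazy":
        return [m for m in sets if not any(o < m for o in sets)]
    if policy == "all":
        return sets
    raise ValueError(f"unknown policy {policy!r}")


def _sort_matches(sets: Iterable[frozenset]) -> list:
    return sorted(sets, key=lambda m: (min(m), -len(m), tuple(sorted(m))))


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def segment_matches(graph: GlycanGraph,
                    segment: Sequence[PatternElement],
                    segment_id: int = 0) -> list:
    """All embeddings of a plain pattern segment (no quantifiers) in a glycan.

    Every occurrence is returned, including overlapping ones.  Wildcards
    match any residue, linkage alternation any listed linkage, unknown
    linkage components match anything in either direction.
    """
    for el in segment:
        if el.lookaround != "none":
            raise ValueError("plain segments cannot contain lookaround groups")
        if not el.quantifier.is_default:
            raise ValueError("plain segments cannot contain quantified elements")
    items = _compile_elements(segment, "main")
    seen = set()
    out = []
    for r in graph.residues:
        for asg, leaf in _embed(graph, items, None, pin_root=r):
            nodes = frozenset(asg)
            if nodes in seen:
                continue
            seen.add(nodes)
            out.append(SegmentMatch(segment_id, nodes, (leaf, r)))
    out.sort(key=lambda m: (min(m.node_set), -len(m.node_set),
                            tuple(sorted(m.node_set))))
    return out


def check_counts(graph: GlycanGraph, constraint: CountConstraint,
                 anchor: int | SegmentMatch | None = None) -> list:
    """Chains of ``c`` consecutive repeat-unit embeddings, ``c`` allowed.

    ``anchor`` fixes the residue the chain's rootward end must attach to
    (an index, or a :class:`SegmentMatch` whose leafward attachment is
    used); ``None`` leaves the attachment free.  ``c = 0`` contributes a
    single empty candidate when allowed.  Returns ``(node_set, count)``
    pairs, deduplicated.
    """
    if isinstance(anchor, SegmentMatch):
        anchor = anchor.attachment[0]
    items_cache: dict[int, tuple] = {}

    def unit_items(c: int) -> tuple:
        if c not in items_cache:
            items_cache[c] = _compile_elements(constraint.unit, "main") * c
        return items_cache[c]

    out = []
    seen = set()
    for c in sorted(constraint.allowed_counts):
        if c == 0:
            if (frozenset(), 0) not in seen:
                seen.add((frozenset(), 0))
                out.append((frozenset(), 0))
            continue
        if c > graph.n_residues:
            continue
        for asg, _ in _embed(graph, unit_items(c), attach_to=anchor):
            key = (frozenset(asg), c)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def trace_match(graph: GlycanGraph, ast: PatternAST,
                policy: str = "greedy") -> list:
    """Full pattern matching: connected node-index lists, policy-filtered.

    Each returned list induces a connected subgraph, satisfies every
    element's count constraint, contains the intervening linkage nodes,
    and excludes lookaround nodes.  Under ``greedy`` (default) only
    count-maximal matches are reported, under ``lazy`` count-minimal ones;
    duplicates are removed and results are sorted by lowest node index
    (ties: larger match first).
    """
    assignments = _all_assignments(graph, ast)
    kept = _apply_policy(assignments.keys(), policy)
    return [sorted(m) for m in _sort_matches(kept)]


def _trim_for_serialization(graph: GlycanGraph, nodes: Sequence[int]) -> frozenset:
    """Drop rootward-dangling linkage nodes so the set serializes cleanly."""
    keep = set(nodes)
    for i in nodes:
        if graph.is_linkage(i) and graph.parent.get(i) not in keep:
            keep.discard(i)
    return frozenset(keep)


def get_match(pattern: str, glycan: str, policy: str = "greedy") -> MatchResult:
    """Probe one glycan with one glyco-regex pattern.

    Parses both inputs, traces all matches and serializes each matched
    sub-glycan.  Returns an empty result (no error) when the pattern does
    not occur.  Parse failures carry a message identifying which input was
    at fault.
    """
    try:
        ast = parse_pattern(pattern)
    except GlyreError as e:
        raise PatternParseError(f"invalid pattern {pattern!r}: {e}") from e
    try:
        g = parse_iupac(glycan)
    except GlyreError as e:
        raise GlycanParseError(f"invalid glycan {glycan!r}: {e}") from e
    matches = trace_match(g, ast, policy)
    strings = tuple(
        to_string(g, _trim_for_serialization(g, m)) for m in matches
    )
    return MatchResult(
        glycan=to_string(g),
        matches=tuple(tuple(m) for m in matches),
        match_strings=strings,
    )
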