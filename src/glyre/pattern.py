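"""The glyco-regex pattern dialect: tokenizer, parser and AST.

Patterns are written in the same direction as IUPAC-condensed glycans,
non-reducing end first.  Element syntax:

* ``Gal``, ``GlcNAc`` ...        exact monosaccharide
* ``Mana6`` / ``Galb3/4``        shorthand linkage: anomer + acceptor
  carbon(s); the donor carbon is inferred from the monosaccharide (C2 for
  sialic acids and other ulosonic acids, C1 otherwise)
* ``Neu5Aca2-3``                 full linkage, as in glycan strings
* ``.`` or ``Monosaccharide``    complete wildcard (any residue)
* ``!Fuc``                       negation: one residue that is *not* Fuc
* ``(...)X``                     a side branch attached to residue X
* ``(...)``\\ +quantifier        a repeat unit along the chain
* ``?  *  +  {n}  {n,m}  {n,}``  quantifiers; a trailing ``?`` makes the
  quantifier lazy (``+?``, ``??`` ...)
* ``(?<=...)`` / ``(?=...)``     lookbehind (pattern start only) and
  lookahead (pattern end only); matched but excluded from results

Whitespace is insignificant (``! Fuc`` equals ``!Fuc``).  The full grammar
is documented in ``docs/grammar.md``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .glycan_io import (
    GlyreError,
    GlycanGraph,
    LinkageLabel,
    normalize_dialect,
    parse_iupac,
)

__all__ = [
    "PatternParseError",
    "LabelSpec",
    "Quantifier",
    "PatternElement",
    "PatternAST",
    "CountConstraint",
    "parse_pattern",
    "infer_linkage",
    "expand_quantified",
    "linkage_matches",
    "DEFAULT_C2_PREFIXES",
]


class PatternParseError(GlyreError, ValueError):
    """Raised when a glyco-regex pattern cannot be parsed."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (offset {offset})"
        super().__init__(message)


# --------------------------------------------------------------------------
# linkage inference
# --------------------------------------------------------------------------

#: residues whose glycosidic bond starts from C2 rather than C1 (ulosonic
#: acids: sialic acids, Kdn/Kdo and relatives), matched by name prefix.
DEFAULT_C2_PREFIXES = ("Neu", "Kdn", "Kdo", "Leg", "Pse", "Aci", "Sia")

# shorthand linkage as used in patterns: anomer, optional donor carbon,
# acceptor carbon, optional alternation ("a6", "b3/4", "a2-3", "?1-?")
_SHORTHAND_RE = re.compile(r"([abq?])(?:([12?])-)?([1-9?])((?:/[1-9])*)")


def _donor_carbon(mono: str | None, c2_prefixes: Sequence[str]) -> int | None:
    if mono is None:
        return None
    return 2 if mono.startswith(tuple(c2_prefixes)) else 1


def infer_linkage(mono: str | None, shorthand: str,
                  c2_prefixes: Sequence[str] = DEFAULT_C2_PREFIXES) -> frozenset:
    """Expand a shorthand linkage spec into a set of :class:`LinkageLabel`.

    The donor carbon, when omitted, is inferred from the monosaccharide:
    C2 for ulosonic acids (``Neu5Ac``, ``Neu5Gc``, ``Kdn``, ... —
    configurable via ``c2_prefixes``), C1 otherwise; ``mono=None``
    (wildcard or negated residue) leaves it unknown.  An empty shorthand
    yields the fully unknown linkage under the same donor rule.

    >>> sorted(str(l) for l in infer_linkage("Man", "a6"))
    ['a1-6']
    >>> sorted(str(l) for l in infer_linkage("Gal", "b3/4"))
    ['b1-3', 'b1-4']
    >>> sorted(str(l) for l in infer_linkage("Neu5Ac", "a3"))
    ['a2-3']
    """
    donor = _donor_carbon(mono, c2_prefixes)
    if not shorthand:
        return frozenset({LinkageLabel("?", donor, None)})
    m = _SHORTHAND_RE.fullmatch(shorthand)
    if m is None:
        raise PatternParseError(f"malformed linkage spec {shorthand!r}")
    anomer = "?" if m.group(1) == "q" else m.group(1)
    cfrom = m.group(2)
    cfrom = donor if cfrom is None else (None if cfrom == "?" else int(cfrom))
    carbons = [m.group(3)] + [x for x in m.group(4).split("/") if x]
    out = set()
    for c in carbons:
        cto = None if c == "?" else int(c)
        out.add(LinkageLabel(anomer, cfrom, cto))
    return frozenset(out)


# --------------------------------------------------------------------------
# AST types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelSpec:
    """What a single pattern position may match.

    ``kind`` is ``exact`` (token in ``tokens``), ``wildcard`` (any residue)
    or ``negated`` (any residue whose token is not in ``tokens``);
    ``linkage`` constrains the linkage from the matched residue toward the
    reducing end (``None`` = any linkage).
    """

    kind: str
    tokens: frozenset = frozenset()
    linkage: frozenset | None = None

    def __post_init__(self):
        if self.kind not in ("exact", "wildcard", "negated", "alternation"):
            raise ValueError(f"invalid LabelSpec kind {self.kind!r}")
        if self.kind in ("exact", "negated", "alternation") and not self.tokens:
            raise ValueError(f"{self.kind} LabelSpec requires tokens")

    def matches_token(self, token: str) -> bool:
        if self.kind == "wildcard":
            return True
        if self.kind == "negated":
            return token not in self.tokens
        return token in self.tokens


@dataclass(frozen=True)
class Quantifier:
    """Allowed repeat counts for a pattern element; ``max_count=None`` = unbounded."""

    min_count: int = 1
    max_count: int | None = 1
    lazy: bool = False

    def __post_init__(self):
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if self.max_count is not None and self.max_count < self.min_count:
            raise ValueError("max_count must be >= min_count")

    @property
    def is_default(self) -> bool:
        return self.min_count == 1 and self.max_count == 1

    def counts(self, ceiling: int) -> range:
        hi = ceiling if self.max_count is None else min(self.max_count, ceiling)
        return range(self.min_count, hi + 1)


ONE = Quantifier(1, 1, False)


@dataclass(frozen=True)
class PatternElement:
    """One element of a pattern: a residue position or a parenthesized group."""

    kind: str  # 'residue' | 'group'
    spec: LabelSpec | None = None
    children: tuple = ()          # tuple of element tuples (groups only)
    quantifier: Quantifier = ONE
    lookaround: str = "none"      # 'none' | 'ahead' | 'behind'

    def __post_init__(self):
        if self.kind == "residue" and self.spec is None:
            raise ValueError("residue element requires a LabelSpec")
        if self.kind == "group" and not self.children:
            raise ValueError("group element requires children")
        if self.lookaround != "none" and not self.quantifier.is_default:
            raise ValueError("lookaround elements cannot be quantified")


@dataclass(frozen=True)
class PatternAST:
    """An ordered glyco-regex pattern, non-reducing to reducing direction."""

    elements: tuple

    def __post_init__(self):
        if not any(e.lookaround == "none" for e in self.elements):
            raise ValueError("pattern needs at least one non-lookaround element")

    def explain(self) -> str:
        """Human-readable chunked view of the pattern (used by ``glyre explain``)."""
        lines = []

        def describe(el: PatternElement, indent: str):
            if el.kind == "residue":
                spec = el.spec
                if spec.kind == "wildcard":
                    what = "any monosaccharide"
                elif spec.kind == "negated":
                    what = "not " + "/".join(sorted(spec.tokens))
                else:
                    what = "/".join(sorted(spec.tokens))
                link = ("any linkage" if spec.linkage is None
                        else "/".join(sorted(str(l) for l in spec.linkage)))
                q = el.quantifier
                qtxt = "" if q.is_default else (
                    f"  x{{{q.min_count},{'inf' if q.max_count is None else q.max_count}}}"
                    + (" lazy" if q.lazy else ""))
                tag = "" if el.lookaround == "none" else f"  [look{el.lookaround}]"
                lines.append(f"{indent}residue {what}  ({link}){qtxt}{tag}")
            else:
                q = el.quantifier
                if el.lookaround != "none":
                    head = f"look{el.lookaround}"
                elif q.is_default:
                    head = "branch"
                else:
                    head = (f"repeat x{{{q.min_count},"
                            f"{'inf' if q.max_count is None else q.max_count}}}"
                            + (" lazy" if q.lazy else ""))
                lines.append(f"{indent}{head}:")
                for alt in el.children:
                    for sub in alt:
                        describe(sub, indent + "  ")

        for el in self.elements:
            describe(el, "")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# label/linkage compatibility — the matching semantics of the AST
# --------------------------------------------------------------------------

def _link_compatible(p: LinkageLabel, g: LinkageLabel) -> bool:
    """Two linkage labels are compatible if no known component disagrees.

    Unknown (``?``) components on either side match anything; acceptor
    alternation (``3/4``) matches when the carbon sets intersect.
    """
    if p.anomer != "?" and g.anomer != "?" and p.anomer != g.anomer:
        return False
    if (p.carbon_from is not None and g.carbon_from is not None
            and p.carbon_from != g.carbon_from):
        return False
    pa, ga = p.acceptor_carbons(), g.acceptor_carbons()
    if pa is not None and ga is not None and not (pa & ga):
        return False
    return True


def linkage_matches(spec: frozenset | None, label: LinkageLabel) -> bool:
    """Does a glycan linkage label satisfy a pattern linkage spec?

    ``spec`` is a set of admissible :class:`LinkageLabel` alternatives
    (``None`` = unconstrained).
    """
    if spec is None:
        return True
    return any(_link_compatible(p, label) for p in spec)


# --------------------------------------------------------------------------
# pattern parsing
# --------------------------------------------------------------------------

_QUANT_OPEN = "?*+{"
_RUN_CHARS = re.compile(r"[A-Za-z0-9?/\-]")
_BRACE_RE = re.compile(r"\{(\d+)(,(\d*))?\}")


def _scan_quantifier(s: str, pos: int):
    """Try to read a quantifier at ``pos``; returns (Quantifier | None, new_pos)."""
    if pos >= len(s):
        return None, pos
    ch = s[pos]
    if ch == "?":
        q = (0, 1)
        pos += 1
    elif ch == "*":
        q = (0, None)
        pos += 1
    elif ch == "+":
        q = (1, None)
        pos += 1
    elif ch == "{":
        m = _BRACE_RE.match(s, pos)
        if m is None:
            raise PatternParseError("malformed {n,m} quantifier", offset=pos)
        n = int(m.group(1))
        if m.group(2) is None:
            q = (n, n)
        elif m.group(3) == "":
            q = (n, None)
        else:
            mx = int(m.group(3))
            if n > mx:
                raise PatternParseError(
                    f"quantifier {{{n},{mx}}} has min > max", offset=pos)
            q = (n, mx)
        pos = m.end()
    else:
        return None, pos
    lazy = False
    if pos < len(s) and s[pos] == "?":
        lazy = True
        pos += 1
    return Quantifier(q[0], q[1], lazy), pos


def _acceptable_link(m: re.Match) -> bool:
    """An unknown acceptor carbon requires the full ``?1-?`` spelling;
    otherwise ``Gal??`` (lazy-optional Gal) would read as a linkage."""
    return m.group(2) is not None or m.group(3) != "?"


def _link_end_ok(s: str, end: int) -> bool:
    """A linkage inside an element run must be followed by an element
    boundary: uppercase residue start, a non-run character, a quantifier,
    or the end of the pattern."""
    if end >= len(s):
        return True
    ch = s[end]
    if ch.isupper():
        return True
    if ch in _QUANT_OPEN:
        return True
    if not _RUN_CHARS.match(ch):
        return True
    return False


_RES_TOKEN_RE = re.compile(r"[A-Z][A-Za-z0-9]*")


def _scan_named_element(s: str, pos: int, c2_prefixes):
    """Read one named-residue element (token + optional linkage shorthand)."""
    j = pos
    while j < len(s) and _RUN_CHARS.match(s[j]):
        j += 1
    run_end = j
    # find the leftmost linkage spec inside the run that ends at a boundary
    for k in range(pos + 1, run_end):
        m = _SHORTHAND_RE.match(s, k)
        if m and _acceptable_link(m) and m.end() <= run_end and _link_end_ok(s, m.end()):
            token = s[pos:k]
            if _RES_TOKEN_RE.fullmatch(token):
                return token, s[k:m.end()], m.end()
    m = _RES_TOKEN_RE.match(s, pos)
    if m is None:
        raise PatternParseError(
            f"expected a monosaccharide token, found {s[pos:pos+8]!r}", offset=pos)
    return m.group(0), "", m.end()


def _parse_elements(s: str, pos: int, c2_prefixes, depth: int):
    """Parse a sequence of elements until ')' or end; returns (elements, pos)."""
    elements: list[PatternElement] = []
    while pos < len(s) and s[pos] != ")":
        if s.startswith("(?<=", pos) or s.startswith("(?=", pos):
            look = "behind" if s[pos + 2] == "<" else "ahead"
            open_off = pos
            if depth > 0:
                raise PatternParseError(
                    "lookaround groups are only allowed at the top level",
                    offset=open_off)
            pos += 4 if look == "behind" else 3
            body, pos = _parse_elements(s, pos, c2_prefixes, depth + 1)
            if pos >= len(s) or s[pos] != ")":
                raise PatternParseError("unbalanced parentheses", offset=open_off)
            pos += 1
            if not body:
                raise PatternParseError("empty lookaround group", offset=open_off)
            q, qpos = _scan_quantifier(s, pos)
            if q is not None:
                raise PatternParseError(
                    "lookaround groups cannot be quantified", offset=pos)
            elements.append(PatternElement(
                "group", children=(tuple(body),), lookaround=look))
            continue
        if s[pos] == "(":
            open_off = pos
            body, pos = _parse_elements(s, pos + 1, c2_prefixes, depth + 1)
            if pos >= len(s) or s[pos] != ")":
                raise PatternParseError("unbalanced parentheses", offset=open_off)
            pos += 1
            if not body:
                raise PatternParseError("empty group", offset=open_off)
            q, pos = _scan_quantifier(s, pos)
            if q is not None and q.min_count == 1 and q.max_count == 1:
                # "(X){1}" is the chain X itself, not a side branch
                elements.extend(body)
            else:
                elements.append(PatternElement(
                    "group", children=(tuple(body),),
                    quantifier=q if q is not None else ONE))
            continue
        if s[pos] in _QUANT_OPEN:
            raise PatternParseError(
                "dangling quantifier: nothing to quantify", offset=pos)
        negated = False
        if s[pos] == "!":
            negated = True
            pos += 1
            if pos >= len(s):
                raise PatternParseError("dangling negation", offset=pos)
        if s[pos] == ".":
            token = "."
            pos += 1
            shorthand = ""
            m = _SHORTHAND_RE.match(s, pos)
            if m and _acceptable_link(m) and _link_end_ok(s, m.end()):
                shorthand = m.group(0)
                pos = m.end()
        else:
            token, shorthand, pos = _scan_named_element(s, pos, c2_prefixes)
        wildcard = token in (".", "Monosaccharide")
        if wildcard and negated:
            raise PatternParseError("cannot negate a wildcard", offset=pos)
        link = (infer_linkage(None if (wildcard or negated) else token,
                              shorthand, c2_prefixes)
                if shorthand else None)
        if wildcard:
            spec = LabelSpec("wildcard", linkage=link)
        elif negated:
            spec = LabelSpec("negated", tokens=frozenset({token}), linkage=link)
        else:
            spec = LabelSpec("exact", tokens=frozenset({token}), linkage=link)
        q, pos = _scan_quantifier(s, pos)
        elements.append(PatternElement(
            "residue", spec=spec, quantifier=q if q is not None else ONE))
    return elements, pos


def parse_pattern(pattern_string: str,
                  c2_prefixes: Sequence[str] = DEFAULT_C2_PREFIXES) -> PatternAST:
    """Parse a glyco-regex pattern string into a :class:`PatternAST`.

    Raises :class:`PatternParseError` (with the character offset) on
    malformed input: unbalanced parentheses, dangling quantifiers,
    lookbehind not at the pattern start, lookahead not at the pattern end,
    or ``{n,m}`` with ``n > m``.
    """
    s = normalize_dialect(pattern_string)
    if not s:
        raise PatternParseError("empty pattern")
    elements, pos = _parse_elements(s, 0, tuple(c2_prefixes), 0)
    if pos < len(s):
        raise PatternParseError("unbalanced parentheses", offset=pos)
    # lookaround placement: lookbehind only as a prefix, lookahead only as
    # a suffix, at most one of each
    kinds = [e.lookaround for e in elements]
    n_behind = kinds.count("behind")
    n_ahead = kinds.count("ahead")
    if n_behind > 1:
        raise PatternParseError("multiple lookbehind groups")
    if n_ahead > 1:
        raise PatternParseError("multiple lookahead groups")
    if n_behind and kinds[0] != "behind":
        raise PatternParseError("lookbehind must be at the pattern start")
    if n_ahead and kinds[-1] != "ahead":
        raise PatternParseError("lookahead must be at the pattern end")
    _check_branch_attachment(elements)
    try:
        return PatternAST(tuple(elements))
    except ValueError as e:
        raise PatternParseError(str(e)) from e


def _check_branch_attachment(elements: Sequence[PatternElement]) -> None:
    """Every branch group must be followed by an unquantified residue."""
    pending = False
    for el in elements:
        if el.kind == "group" and el.lookaround == "none" and el.quantifier.is_default:
            pending = True
            _check_branch_attachment(el.children[0])
            continue
        if pending and not (el.kind == "residue" and el.quantifier.is_default):
            raise PatternParseError(
                "a branch group must be followed by an unquantified residue")
        pending = False
        if el.kind == "group":
            _check_branch_attachment(el.children[0])
    if pending:
        raise PatternParseError("a branch group must be followed by a residue")


# --------------------------------------------------------------------------
# quantified elements as count constraints
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CountConstraint:
    """A repeat unit plus its set of allowed repeat counts.

    ``substructure`` is the repeat unit rendered as a glycan graph when the
    unit is concrete (exact residues, single linkages); wildcard-bearing
    units cannot be rendered and leave it ``None``.  ``unit`` retains the
    authoritative pattern elements, ``attachment_linkage`` the unit's
    trailing linkage spec (the bond to the next repeat or chain element).
    """

    unit: tuple
    allowed_counts: frozenset
    substructure: GlycanGraph | None = None
    attachment_linkage: frozenset | None = None
    lazy: bool = False

    def __post_init__(self):
        if not self.allowed_counts:
            raise ValueError("allowed_counts must be non-empty")
        if not self.unit:
            raise ValueError("repeat unit must be non-empty")


def _unit_graph(elements: Sequence[PatternElement]) -> GlycanGraph | None:
    """Render a concrete repeat unit as a glycan graph, if possible."""
    parts = []
    for i, el in enumerate(elements):
        if el.kind != "residue" or el.spec.kind != "exact" or not el.quantifier.is_default:
            return None
        (token,) = el.spec.tokens
        parts.append(token)
        last = i == len(elements) - 1
        if not last:
            if el.spec.linkage is None or len(el.spec.linkage) != 1:
                return None
            (link,) = el.spec.linkage
            parts.append(str(link))
    try:
        return parse_iupac("".join(parts))
    except GlyreError:
        return None


def expand_quantified(element: PatternElement,
                      ceiling: int | None = None) -> CountConstraint:
    """Turn a quantified element into a ``(substructure: allowed counts)`` entry.

    ``ceiling`` bounds unbounded quantifiers (``*``, ``+``, ``{n,}``); it is
    normally the glycan's residue count, supplied by the caller at match
    time.  For a group element the repeat unit is the group body; for a
    residue element it is the residue itself.
    """
    q = element.quantifier
    if q.max_count is None and ceiling is None:
        raise ValueError("unbounded quantifier needs a ceiling")
    hi = q.max_count if q.max_count is not None else ceiling
    if ceiling is not None:
        hi = min(hi, ceiling)
    counts = frozenset(range(q.min_count, hi + 1))
    if not counts:
        counts = frozenset({q.min_count})
    if element.kind == "group":
        unit = element.children[0]
    else:
        unit = (PatternElement("residue", spec=element.spec),)
    trailing = unit[-1].spec.linkage if unit[-1].kind == "residue" else None
    return CountConstraint(
        unit=tuple(unit),
        allowed_counts=counts,
        substructure=_unit_graph(unit),
        attachment_linkage=trailing,
        lazy=q.lazy,
    )
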