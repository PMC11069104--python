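"""IUPAC-condensed glycan structures as alternating residue/linkage trees.

A glycan is a rooted tree of monosaccharides joined by glycosidic linkages.
IUPAC-condensed notation writes the tree from the non-reducing end (leaves)
to the reducing end (root), with side branches in parentheses, e.g. the
sialyl Lewis x motif ``Neu5Aca2-3Galb1-4(Fuca1-3)GlcNAc``.

This module parses such strings into :class:`GlycanGraph` objects in which
*both* monosaccharides and linkages are nodes (so that pattern-matching
operations can address linkages by index), serializes graphs back to a
canonical string, and extracts connected sub-glycans.

Conventions
-----------
* Node indices are 0-based token positions in the canonical serialized
  string, read left (non-reducing) to right (reducing end); parentheses do
  not count as tokens.
* Edges point child -> parent, i.e. toward the reducing end; the root is
  the reducing-end monosaccharide.
* Unicode spellings (alpha/beta letters, en/em dashes) are normalized to
  ASCII (``a``/``b``, ``-``) before tokenization; whitespace is ignored.
* At a branch point the canonical serialization writes the branch with the
  longest residue path outside parentheses (ties broken by lowest acceptor
  carbon of the connecting linkage, then lexicographically); this makes
  serialization deterministic and round-trip idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "GlyreError",
    "GlycanParseError",
    "LinkageLabel",
    "GlycanGraph",
    "normalize_dialect",
    "parse_iupac",
    "to_string",
    "subgraph",
    "read_glycans",
    "read_glycan_column",
]


class GlyreError(Exception):
    """Base class for all errors raised by glyre."""


class GlycanParseError(GlyreError, ValueError):
    """Raised when an IUPAC-condensed glycan string cannot be parsed."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (offset {offset})"
        super().__init__(message)


_UNICODE_MAP = str.maketrans({
    "α": "a",   # alpha
    "β": "b",   # beta
    "–": "-",   # en dash
    "—": "-",   # em dash
    "−": "-",   # minus sign
})


def normalize_dialect(text: str) -> str:
    """Normalize a glycan or pattern string to the ASCII dialect.

    Greek anomer letters become ``a``/``b``, typographic dashes become
    ``-`` and all whitespace is removed.
    """
    return re.sub(r"\s+", "", text.translate(_UNICODE_MAP))


# --------------------------------------------------------------------------
# linkage labels
# --------------------------------------------------------------------------

# full linkage token inside a glycan string, e.g. "b1-4", "?1-?", "a1-3/6"
_LINK_TOKEN_RE = re.compile(r"([abq?])([12?])-([1-9?])((?:/[1-9])*)")


@dataclass(frozen=True)
class LinkageLabel:
    """A glycosidic linkage: anomeric configuration plus donor/acceptor carbons.

    ``anomer`` is ``'a'``, ``'b'`` or ``'?'`` (unknown); ``carbon_from`` is the
    donor (anomeric) carbon, 1 or 2, or ``None`` when unknown; ``carbon_to``
    is the acceptor carbon 1-9 or ``None`` when unknown.  ``alternatives``
    holds extra acceptor carbons for in-glycan ambiguity such as ``a1-3/6``.
    """

    anomer: str
    carbon_from: int | None
    carbon_to: int | None
    alternatives: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.anomer not in ("a", "b", "?"):
            raise ValueError(f"invalid anomer {self.anomer!r}")
        if self.carbon_from not in (1, 2, None):
            raise ValueError(f"invalid donor carbon {self.carbon_from!r}")
        if self.carbon_to is not None and not 1 <= self.carbon_to <= 9:
            raise ValueError(f"invalid acceptor carbon {self.carbon_to!r}")
        if self.carbon_to in self.alternatives:
            object.__setattr__(
                self, "alternatives", self.alternatives - {self.carbon_to}
            )

    def acceptor_carbons(self) -> frozenset[int] | None:
        """All admissible acceptor carbons, or ``None`` when fully unknown."""
        if self.carbon_to is None:
            return None
        return frozenset({self.carbon_to}) | self.alternatives

    @classmethod
    def from_token(cls, token: str) -> "LinkageLabel":
        m = _LINK_TOKEN_RE.fullmatch(token)
        if m is None:
            raise ValueError(f"not a linkage token: {token!r}")
        anomer = "?" if m.group(1) == "q" else m.group(1)
        cfrom = None if m.group(2) == "?" else int(m.group(2))
        cto = None if m.group(3) == "?" else int(m.group(3))
        alts = frozenset(int(x) for x in m.group(4).split("/") if x)
        return cls(anomer, cfrom, cto, alts)

    def __str__(self) -> str:
        cf = "?" if self.carbon_from is None else str(self.carbon_from)
        ct = "?" if self.carbon_to is None else str(self.carbon_to)
        alts = "".join(f"/{c}" for c in sorted(self.alternatives))
        return f"{self.anomer}{cf}-{ct}{alts}"


#: serialized form of a completely unknown linkage
UNKNOWN_LINKAGE = LinkageLabel("?", 1, None)


# --------------------------------------------------------------------------
# the glycan graph
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GlycanGraph:
    """Rooted tree with alternating monosaccharide and linkage nodes.

    ``labels[i]`` is a residue token (``str``) or a :class:`LinkageLabel`;
    ``parent`` maps every non-root node to its parent (toward the reducing
    end).  ``source_indices``, when present, maps this graph's indices back
    to the indices of the graph it was cut from (see :func:`subgraph`).
    """

    labels: tuple
    parent: dict
    root_index: int
    source_indices: tuple | None = None

    # -- structure ---------------------------------------------------------

    @cached_property
    def _children(self) -> dict:
        ch: dict[int, list[int]] = {i: [] for i in range(len(self.labels))}
        for c, p in self.parent.items():
            ch[p].append(c)
        return {i: tuple(sorted(v)) for i, v in ch.items()}

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_residues(self) -> int:
        return sum(1 for lab in self.labels if isinstance(lab, str))

    def is_linkage(self, i: int) -> bool:
        return isinstance(self.labels[i], LinkageLabel)

    @cached_property
    def residues(self) -> tuple:
        return tuple(i for i in range(len(self.labels)) if not self.is_linkage(i))

    def children(self, i: int) -> tuple:
        return self._children[i]

    def residue_children(self, r: int) -> list:
        """``(linkage_index, child_residue_index)`` pairs below residue ``r``."""
        out = []
        for link in self.children(r):
            for child in self.children(link):
                out.append((link, child))
        return out

    def residue_parent(self, r: int):
        """``(linkage_index, parent_residue_index)`` above ``r``, or ``None``."""
        link = self.parent.get(r)
        if link is None:
            return None
        return (link, self.parent[link])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for i, lab in enumerate(self.labels):
            g.add_node(i, label=str(lab), kind="linkage" if self.is_linkage(i) else "residue")
        g.add_edges_from(self.parent.items())
        return g

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        """Assert the tree, alternation and indexing invariants."""
        n = self.n_nodes
        if n == 0:
            raise ValueError("empty graph")
        roots = [i for i in range(n) if i not in self.parent]
        if roots != [self.root_index]:
            raise ValueError(f"expected single root {self.root_index}, found {roots}")
        if self.is_linkage(self.root_index):
            raise ValueError("root must be a monosaccharide")
        for c, p in self.parent.items():
            if self.is_linkage(c) == self.is_linkage(p):
                raise ValueError(f"edge {c}->{p} violates residue/linkage alternation")
        for i in range(n):
            if self.is_linkage(i):
                kids = self.children(i)
                if len(kids) != 1:
                    raise ValueError(f"linkage node {i} must have exactly one child")
        if self.n_residues * 2 - 1 != n:
            raise ValueError("node count is not 2k-1 for k residues")

    def __str__(self) -> str:
        return to_string(self)


# --------------------------------------------------------------------------
# tokenization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Token:
    kind: str   # 'residue' | 'linkage' | 'lparen' | 'rparen'
    value: str
    offset: int
    index: int = -1  # node index for residue/linkage tokens


def _tokenize(s: str) -> list:
    toks = []
    i = 0
    nidx = 0
    while i < len(s):
        ch = s[i]
        if ch == "(":
            toks.append(_Token("lparen", ch, i))
            i += 1
            continue
        if ch == ")":
            toks.append(_Token("rparen", ch, i))
            i += 1
            continue
        m = _LINK_TOKEN_RE.match(s, i)
        if m:
            toks.append(_Token("linkage", m.group(0), i, nidx))
            nidx += 1
            i = m.end()
            continue
        j = i
        while j < len(s) and (s[j].isalnum() or s[j] in "?',_") and not _LINK_TOKEN_RE.match(s, j):
            j += 1
        if j == i:
            raise GlycanParseError(f"unexpected character {ch!r}", offset=i)
        toks.append(_Token("residue", s[i:j], i, nidx))
        nidx += 1
        i = j
    return toks


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

def _build_graph(toks: Sequence[_Token]) -> GlycanGraph:
    """Build a GlycanGraph from a token stream (indices = token order)."""
    labels: list = [None] * sum(1 for t in toks if t.index >= 0)
    for t in toks:
        if t.kind == "residue":
            labels[t.index] = t.value
        elif t.kind == "linkage":
            labels[t.index] = LinkageLabel.from_token(t.value)
    parent: dict[int, int] = {}

    def parse_chain(i: int):
        """Parse one chain; returns (root_residue_idx, trailing_link_idx, next_pos)."""
        pending: list[tuple[int, int]] = []   # (child_residue, linkage) awaiting parent
        while True:
            while i < len(toks) and toks[i].kind == "lparen":
                open_off = toks[i].offset
                broot, blink, i = parse_chain(i + 1)
                if i >= len(toks) or toks[i].kind != "rparen":
                    raise GlycanParseError("unbalanced parentheses", offset=open_off)
                if blink is None:
                    raise GlycanParseError(
                        "branch must end with a linkage", offset=toks[i].offset)
                pending.append((broot, blink))
                i += 1
            if i >= len(toks) or toks[i].kind != "residue":
                if i < len(toks) and toks[i].kind == "linkage":
                    raise GlycanParseError(
                        "expected a residue token", offset=toks[i].offset)
                off = toks[i].offset if i < len(toks) else toks[-1].offset
                raise GlycanParseError("expected a residue token", offset=off)
            r = toks[i].index
            i += 1
            for child, link in pending:
                parent[link] = r
                parent[child] = link
            pending = []
            if i >= len(toks) or toks[i].kind == "rparen":
                return r, None, i
            if toks[i].kind == "linkage":
                link = toks[i].index
                i += 1
                if i >= len(toks) or toks[i].kind == "rparen":
                    return r, link, i
                pending = [(r, link)]
                continue
            if toks[i].kind == "residue":
                raise GlycanParseError(
                    "two adjacent residue tokens with no linkage",
                    offset=toks[i].offset)
            raise GlycanParseError(
                "branch must follow a linkage", offset=toks[i].offset)

    root, trailing, i = parse_chain(0)
    if i < len(toks):
        raise GlycanParseError("unbalanced parentheses", offset=toks[i].offset)
    if trailing is not None:
        raise GlycanParseError("glycan ends with a dangling linkage")
    g = GlycanGraph(tuple(labels), parent, root)
    g.validate()
    return g


def parse_iupac(glycan_string: str) -> GlycanGraph:
    """Parse an IUPAC-condensed glycan string into a canonical :class:`GlycanGraph`.

    Both the Unicode dialect (``Neu5Acα2-3Galβ1-4(Fucα1-3)GlcNAc``) and the
    ASCII dialect are accepted; node indices of the returned graph follow
    the canonical serialization (see :func:`to_string`).
    """
    s = normalize_dialect(glycan_string)
    if not s:
        raise GlycanParseError("empty glycan string")
    raw = _build_graph(_tokenize(s))
    canonical = to_string(raw)
    if canonical == s:
        return raw
    g = _build_graph(_tokenize(canonical))
    g.validate()
    return g


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def _link_sort_value(label: LinkageLabel) -> int:
    carbons = label.acceptor_carbons()
    return min(carbons) if carbons else 10


def _serialize_tokens(graph: GlycanGraph, include: frozenset | None = None):
    """Emit ``(token, original_index)`` pairs for the (sub-)glycan.

    ``include`` restricts serialization to a connected node subset; a
    rootward-dangling linkage (child present, parent absent) is dropped from
    the output, since a valid IUPAC-condensed string must start and end on
    monosaccharides.  Parenthesis tokens carry index ``None``.
    """
    if include is None:
        include = frozenset(range(graph.n_nodes))
    else:
        include = frozenset(include)
        bad = [i for i in include if not 0 <= i < graph.n_nodes]
        if bad:
            raise ValueError(f"node indices out of range: {sorted(bad)}")
    if not include:
        raise ValueError("empty node subset")

    # drop rootward-dangling linkages; reject linkages cut from their child
    kept = set(include)
    for i in include:
        if graph.is_linkage(i):
            kids = [c for c in graph.children(i) if c in include]
            if not kids:
                if graph.parent.get(i) in include:
                    raise ValueError(
                        f"linkage node {i} is cut from its child; "
                        "leafward cut points must be monosaccharides")
                raise ValueError(f"linkage node {i} is split from both endpoints")
            if graph.parent.get(i) not in include:
                kept.discard(i)
    if not kept:
        raise ValueError("subset contains no serializable nodes")

    # connectivity of the requested subset
    und = nx.Graph()
    und.add_nodes_from(include)
    for c, p in graph.parent.items():
        if c in include and p in include:
            und.add_edge(c, p)
    if not nx.is_connected(und):
        raise ValueError("node subset does not induce a connected subgraph")

    tops = [i for i in kept if graph.parent.get(i) not in kept]
    (top,) = tops  # connected subset has exactly one rootward-most kept node

    def depth(r: int) -> int:
        best = 0
        for link, child in graph.residue_children(r):
            if link in kept and child in kept:
                best = max(best, depth(child))
        return best + 1

    def emit(r: int) -> list:
        branches = []
        for link, child in graph.residue_children(r):
            if link not in kept or child not in kept:
                continue
            sub = emit(child) + [(str(graph.labels[link]), link)]
            text = "".join(t for t, _ in sub)
            key = (-depth(child), _link_sort_value(graph.labels[link]),
                   str(graph.labels[child]), text)
            branches.append((key, sub))
        branches.sort(key=lambda b: b[0])
        out: list = []
        for k, (_, sub) in enumerate(branches):
            if k == 0:
                out.extend(sub)
            else:
                out.append(("(", None))
                out.extend(sub)
                out.append((")", None))
        out.append((str(graph.labels[r]), r))
        return out

    return emit(top)


def _to_unicode(token: str) -> str:
    return token.replace("a", "α", 1).replace("b", "β", 1)


def to_string(graph: GlycanGraph, node_subset: Iterable[int] | None = None,
              dialect: str = "ascii") -> str:
    """Serialize a glycan graph (or a connected node subset) canonically.

    With ``node_subset`` only the induced sub-glycan is serialized; the
    subset must be connected and may not cut a linkage from its child.  A
    linkage dangling toward the root is omitted from the string (the string
    must start and end on monosaccharides).  ``dialect`` is ``"ascii"``
    (default) or ``"unicode"`` (α/β anomer letters).
    """
    subset = None if node_subset is None else frozenset(node_subset)
    toks = _serialize_tokens(graph, subset)
    if dialect == "ascii":
        return "".join(t for t, _ in toks)
    if dialect == "unicode":
        out = []
        for t, i in toks:
            if i is not None and graph.is_linkage(i):
                out.append(_to_unicode(t))
            else:
                out.append(t)
        return "".join(out)
    raise ValueError(f"unknown dialect {dialect!r}")


def subgraph(graph: GlycanGraph, node_indices: Iterable[int]) -> GlycanGraph:
    """Cut a connected node subset into a new, canonically re-indexed glycan.

    The returned graph's ``source_indices`` attribute maps each new node
    index to the corresponding node index of ``graph``.  A linkage dangling
    toward the root of ``graph`` is dropped (the sub-glycan must be a valid
    glycan in its own right).
    """
    toks = _serialize_tokens(graph, frozenset(node_indices))
    text = "".join(t for t, _ in toks)
    cut = _build_graph(_tokenize(text))
    cut.validate()
    mapping = tuple(i for _, i in toks if i is not None)
    return GlycanGraph(cut.labels, cut.parent, cut.root_index,
                       source_indices=mapping)


# --------------------------------------------------------------------------
# file input
# --------------------------------------------------------------------------

def read_glycans(path) -> list:
    """Read glycan strings from a plain-text file, one per line.

    Blank lines and ``#`` comments are ignored.
    """
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def read_glycan_column(path, column: str, sep: str | None = None) -> list:
    """Read a named glycan column from a CSV/TSV file."""
    import pandas as pd

    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if column not in df.columns:
        raise KeyError(f"column {column!r} not found in {path}")
    return df[column].astype(str).tolist()
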