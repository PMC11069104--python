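"""Glycan-facing utilities on top of the matching engine.

Two workhorses for real analyses:

* :func:`extract_branch` — pull a designated sequence stretch out of many
  glycans at once, e.g. the α1-6 (or α1-3) arm of N-glycans, by pairing a
  branch pattern with a lookahead on the shared core.  The extracted
  sub-glycans are valid IUPAC-condensed strings and can be fed into any
  downstream analysis in place of the full structures.
* :func:`count_matches` — a glycans × patterns motif-count matrix, the
  hand-off point to enrichment or differential-expression statistics
  (which are deliberately out of scope here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .engine import get_match
from .glycan_io import GlyreError
from .pattern import parse_pattern

__all__ = [
    "BranchQuery",
    "extract_branch",
    "count_matches",
    "N_GLYCAN_CORE",
    "alpha16_arm_query",
    "alpha13_arm_query",
]

logger = logging.getLogger("glyre")

#: the invariant N-glycan trimannosyl-chitobiose stem seen from either arm
N_GLYCAN_CORE = "Manb4GlcNAcb4GlcNAc"


@dataclass(frozen=True)
class BranchQuery:
    """A labeled glyco-regex designed to capture one sequence stretch."""

    pattern: str
    label: str

    def __post_init__(self):
        ast = parse_pattern(self.pattern)  # must parse
        if not any(e.lookaround == "none" for e in ast.elements):
            raise ValueError("query needs at least one non-lookaround element")


def alpha16_arm_query() -> BranchQuery:
    """Everything on the α1-6 arm of an N-glycan (core excluded)."""
    return BranchQuery(f".*Mana6(?={N_GLYCAN_CORE})", "alpha1-6 arm")


def alpha13_arm_query() -> BranchQuery:
    """Everything on the α1-3 arm of an N-glycan (core excluded)."""
    return BranchQuery(f".*Mana3(?={N_GLYCAN_CORE})", "alpha1-3 arm")


def extract_branch(glycan: str, query: BranchQuery,
                   policy: str = "greedy") -> list:
    """Serialized sub-glycans for each match of a branch query.

    Lookahead/lookbehind (core context) nodes are excluded; a linkage left
    dangling at the match's rootward boundary (e.g. the α1-6 bond joining
    an arm to the core) is omitted from the string, which must start and
    end on monosaccharides.  Returns ``[]`` when the branch is absent.
    """
    return list(get_match(query.pattern, glycan, policy).match_strings)


def count_matches(glycans: Sequence[str],
                  queries: Sequence[BranchQuery]) -> pd.DataFrame:
    """Motif-count matrix: rows = glycans, columns = query labels.

    Cell ``(g, p)`` is the number of matches of pattern ``p`` in glycan
    ``g``.  Row and column order follow the input order.  Glycans that
    fail to parse are kept as rows of missing values; the failures are
    logged and recorded in ``result.attrs["failures"]`` rather than
    silently dropped.
    """
    failures: dict[str, str] = {}
    rows = []
    for gl in glycans:
        row = []
        for q in queries:
            if gl in failures:
                row.append(pd.NA)
                continue
            try:
                row.append(len(get_match(q.pattern, gl).matches))
            except GlyreError as e:
                failures[gl] = str(e)
                logger.warning("skipping malformed glycan %r: %s", gl, e)
                row = [pd.NA] * len(queries)
                break
        rows.append(row)
    df = pd.DataFrame(rows, index=list(glycans),
                      columns=[q.label for q in queries], dtype="Int64")
    df.attrs["failures"] = failures
    return df
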