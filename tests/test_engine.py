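"""The matching engine: segment isomorphism, count checking, path tracing."""

import random

import networkx as nx
import pytest

from glyre import (
    GlycanParseError,
    PatternParseError,
    check_counts,
    expand_quantified,
    get_match,
    parse_iupac,
    parse_pattern,
    segment_matches,
    trace_match,
)
from glyre.testkit import FEATURES, brute_force_match, pattern_corpus

from conftest import POLY_LACNAC, SLEX, SLEX_UNICODE


def nodesets(matches):
    return {frozenset(m) for m in matches}


def assert_connected(graph, nodes):
    und = nx.Graph((c, p) for c, p in graph.parent.items()
                   if c in nodes and p in nodes)
    und.add_nodes_from(nodes)
    assert nx.is_connected(und)


class TestSegmentMatches:
    def test_exact_segment(self):
        g = parse_iupac(SLEX)
        seg = parse_pattern("Fuca3GlcNAc").elements
        (m,) = segment_matches(g, seg)
        assert m.node_set == {4, 5, 6}
        assert m.attachment == (4, 6)

    def test_wildcard_matches_every_residue(self, small_corpus):
        seg = parse_pattern(".").elements
        for s in small_corpus[:10]:
            g = parse_iupac(s)
            assert len(segment_matches(g, seg)) == g.n_residues

    def test_absent_token(self):
        assert segment_matches(parse_iupac(SLEX), parse_pattern("Xyl").elements) == []

    def test_rejects_quantified_segment(self):
        with pytest.raises(ValueError):
            segment_matches(parse_iupac(SLEX), parse_pattern("Fuca3?").elements)


class TestCheckCounts:
    TWO_REPEATS = "Galb1-4GlcNAcb1-3Galb1-4GlcNAcb1-3GalNAc"

    def constraint(self, counts):
        (el,) = parse_pattern("(Galb4GlcNAcb3)" + counts).elements
        return expand_quantified(el, ceiling=10)

    def test_tandem_chains(self):
        g = parse_iupac(self.TWO_REPEATS)
        found = check_counts(g, self.constraint("{1,3}"))
        assert {c for _, c in found} == {1, 2}
        for nodes, c in found:
            assert len(nodes) == 4 * c
            assert_connected(g, nodes)

    def test_zero_count_satisfaction(self):
        g = parse_iupac(SLEX)  # the unit is absent here
        found = check_counts(g, self.constraint("{0,1}"))
        assert found == [(frozenset(), 0)]

    def test_unsatisfiable_count(self):
        g = parse_iupac("Galb1-4GlcNAcb1-3GalNAc")  # single repeat only
        assert check_counts(g, self.constraint("{2}")) == []


class TestTraceMatch:
    def test_full_self_match(self):
        res = get_match("Neu5Aca3Galb4(Fuca3)GlcNAc", SLEX_UNICODE)
        assert res.matches == ((0, 1, 2, 3, 4, 5, 6),)

    def test_submatch(self):
        res = get_match("Fuca3GlcNAc", SLEX_UNICODE)
        assert res.matches == ((4, 5, 6),)
        assert res.match_strings == ("Fuca1-3GlcNAc",)

    def test_lookbehind_excludes_context(self):
        plain = get_match("Neu5Aca3Galb4(Fuca3)GlcNAc", SLEX)
        look = get_match("(?<=Neu5Aca3)Galb4(Fuca3)GlcNAc", SLEX)
        assert look.matches == ((2, 3, 4, 5, 6),)
        # exclusion identity: the lookaround match is the plain match minus
        # the Neu5Ac + a2-3 nodes
        assert set(plain.matches[0]) - set(look.matches[0]) == {0, 1}

    def test_lookahead_excludes_context(self):
        res = get_match("Fuca3(?=GlcNAc)", SLEX)
        assert res.matches == ((4, 5),)
        assert res.match_strings == ("Fuc",)

    def test_identity_single_residue(self):
        assert get_match("Gal", "Gal").matches == ((0,),)
        assert get_match(".", "Gal").matches == ((0,),)

    def test_positional_negation(self):
        assert get_match("!Fuca3GlcNAc", SLEX).matches == ()
        assert get_match("!Xyla3GlcNAc", SLEX).matches == ((4, 5, 6),)

    def test_dangling_linkage_requirement(self):
        # "Mana6" needs an a1-6 bond toward the root; the bond is matched
        res = get_match("Mana6", "Mana1-6Manb1-4GlcNAc")
        assert len(res.matches) == 1
        g = parse_iupac("Mana1-6Manb1-4GlcNAc")
        (m,) = res.matches
        assert any(g.is_linkage(i) for i in m)
        assert get_match("Mana6", "Man").matches == ()

    def test_branch_matching_is_string_order_insensitive(self):
        flipped = "Fuca1-3(Neu5Aca2-3Galb1-4)GlcNAc"
        res = get_match("Galb4(Fuca3)GlcNAc", flipped)
        assert len(res.matches) == 1

    def test_greedy_lacnac(self):
        res = get_match("(Galb4GlcNAcb3)+", POLY_LACNAC)
        assert res.matches == (tuple(range(12)),)

    def test_lazy_lacnac(self):
        res = get_match("(Galb4GlcNAcb3)+?", POLY_LACNAC, policy="lazy")
        assert nodesets(res.matches) == {
            frozenset(range(0, 4)), frozenset(range(4, 8)), frozenset(range(8, 12))}

    def test_unknown_linkage_matches_both_ways(self):
        assert get_match("Gal?1-?GlcNAc", "Galb1-4GlcNAc").matches != ()
        assert get_match("Galb4GlcNAc", "Gal?1-?GlcNAc").matches != ()

    def test_error_messages_identify_input(self):
        with pytest.raises(PatternParseError, match="pattern"):
            get_match("*Gal", SLEX)
        with pytest.raises(GlycanParseError, match="glycan"):
            get_match("Gal", "Galb1-4(")

    def test_no_match_is_not_an_error(self):
        res = get_match("Xyl", SLEX)
        assert res.matches == () and res.match_strings == ()


class TestEngineProperties:
    def _pairs(self, corpus, n_per_feature=6, seed=9):
        rng = random.Random(seed)
        out = []
        for feat in FEATURES:
            out.extend(pattern_corpus(feat, corpus[:n_per_feature], rng))
        return out

    def test_matches_are_connected(self, small_corpus):
        for pat, gl in self._pairs(small_corpus):
            g = parse_iupac(gl)
            for policy in ("greedy", "lazy"):
                for m in trace_match(g, parse_pattern(pat), policy):
                    assert_connected(g, set(m))

    def test_greedy_dominance(self, small_corpus):
        """Every lazy match is contained in some greedy match."""
        for pat, gl in self._pairs(small_corpus):
            g = parse_iupac(gl)
            ast = parse_pattern(pat)
            greedy = nodesets(trace_match(g, ast, "greedy"))
            for m in trace_match(g, ast, "lazy"):
                assert any(frozenset(m) <= gm for gm in greedy)

    def test_wildcard_monotonicity(self, tiny_corpus):
        """Replacing an exact residue by a wildcard never loses matches."""
        rng = random.Random(31)
        for gl in tiny_corpus:
            exact = pattern_corpus("plain", [gl], rng)[0][0]
            g = parse_iupac(gl)
            n_exact = len(trace_match(g, parse_pattern(exact), "all"))
            # wildcard every residue token in turn via the parsed AST text
            import re as _re
            for m in _re.finditer(r"[A-Z][A-Za-z0-9]*", exact):
                relaxed = exact[:m.start()] + "." + exact[m.end():]
                n_relaxed = len(trace_match(g, parse_pattern(relaxed), "all"))
                assert n_relaxed >= n_exact

    def test_quantifier_nesting(self):
        """{n,n} matches are a subset of {n,m} matches (all assignments)."""
        g = parse_iupac(POLY_LACNAC)
        for n, m in ((1, 2), (1, 3), (2, 3)):
            tight = nodesets(trace_match(
                g, parse_pattern("(Galb4GlcNAcb3){%d}" % n), "all"))
            loose = nodesets(trace_match(
                g, parse_pattern("(Galb4GlcNAcb3){%d,%d}" % (n, m)), "all"))
            assert tight <= loose

    def test_deterministic_output(self, small_corpus):
        for pat, gl in self._pairs(small_corpus, n_per_feature=3):
            g = parse_iupac(gl)
            ast = parse_pattern(pat)
            assert trace_match(g, ast) == trace_match(g, ast)

    def test_oracle_equivalence_spot_check(self, tiny_corpus):
        """Engine output equals exhaustive enumeration on a mixed corpus."""
        rng = random.Random(13)
        for feat in FEATURES:
            for pat, gl in pattern_corpus(feat, tiny_corpus, rng):
                for policy in ("greedy", "lazy"):
                    engine = nodesets(trace_match(
                        parse_iupac(gl), parse_pattern(pat), policy))
                    oracle = nodesets(brute_force_match(pat, gl, policy))
                    assert engine == oracle, (feat, pat, gl, policy)
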