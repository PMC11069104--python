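"""The glyco-regex grammar: tokenization, AST shape, linkage inference."""

import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyre import (
    LinkageLabel,
    PatternParseError,
    Quantifier,
    expand_quantified,
    infer_linkage,
    parse_pattern,
    to_string,
)
from glyre.pattern import ONE, linkage_matches


def links(spec):
    return sorted(str(l) for l in spec)


class TestElements:
    def test_shorthand_linkage(self):
        ast = parse_pattern("Mana6")
        (el,) = ast.elements
        assert el.kind == "residue"
        assert el.spec.kind == "exact" and el.spec.tokens == {"Man"}
        assert links(el.spec.linkage) == ["a1-6"]
        assert el.quantifier == ONE

    def test_linkage_alternation(self):
        (el,) = parse_pattern("Galb3/4").elements
        assert links(el.spec.linkage) == ["b1-3", "b1-4"]

    def test_full_form_linkage(self):
        (el, el2) = parse_pattern("Neu5Aca2-3Gal").elements
        assert el.spec.tokens == {"Neu5Ac"}
        assert links(el.spec.linkage) == ["a2-3"]
        assert el2.spec.tokens == {"Gal"} and el2.spec.linkage is None

    def test_wildcard_spellings_identical(self):
        assert parse_pattern(".") == parse_pattern("Monosaccharide")
        assert parse_pattern(".a3Gal") == parse_pattern("Monosaccharidea3Gal")

    def test_negation_whitespace_tolerant(self):
        a = parse_pattern("!Fuc")
        b = parse_pattern("! Fuc")
        assert a == b
        (el,) = a.elements
        assert el.spec.kind == "negated" and el.spec.tokens == {"Fuc"}
        assert el.spec.matches_token("Gal") and not el.spec.matches_token("Fuc")

    def test_negated_element_keeps_linkage(self):
        (el, _) = parse_pattern("!Fuca3GlcNAc").elements
        # donor carbon unknown: the matched residue is unknown
        assert links(el.spec.linkage) == ["a?-3"]

    def test_chain_splitting(self):
        ast = parse_pattern("Neu5Aca3Galb4GlcNAc")
        assert [sorted(e.spec.tokens) for e in ast.elements] == [
            ["Neu5Ac"], ["Gal"], ["GlcNAc"]]
        assert links(ast.elements[0].spec.linkage) == ["a2-3"]

    def test_unknown_linkage_element(self):
        (el, _) = parse_pattern("Gal?1-?GlcNAc").elements
        assert links(el.spec.linkage) == ["?1-?"]


class TestQuantifiers:
    @pytest.mark.parametrize("glyph, canonical", [
        ("Gal?", "Gal{0,1}"),
        ("Gal+", "Gal{1,}"),
        ("Gal*", "Gal{0,}"),
    ])
    def test_glyph_algebra(self, glyph, canonical):
        assert parse_pattern(glyph) == parse_pattern(canonical)

    @pytest.mark.parametrize("pattern, mn, mx, lazy", [
        ("Gal{2}", 2, 2, False),
        ("Gal{1,3}", 1, 3, False),
        ("Gal{2,}", 2, None, False),
        ("Gal+?", 1, None, True),
        ("Gal??", 0, 1, True),
        ("Gal{1,3}?", 1, 3, True),
    ])
    def test_counts_and_lazy(self, pattern, mn, mx, lazy):
        (el,) = parse_pattern(pattern).elements
        assert el.quantifier == Quantifier(mn, mx, lazy)

    def test_group_quantifier(self):
        (el,) = parse_pattern("(Galb4GlcNAcb3){1,3}").elements
        assert el.kind == "group" and el.quantifier == Quantifier(1, 3)
        assert len(el.children[0]) == 2

    def test_quantifier_binds_element_with_linkage(self):
        (el, _) = parse_pattern("Fuca3?GlcNAc").elements
        assert el.quantifier == Quantifier(0, 1)
        assert links(el.spec.linkage) == ["a1-3"]


class TestStructure:
    def test_branch_group(self):
        ast = parse_pattern("Galb4(Fuca3)GlcNAc")
        kinds = [e.kind for e in ast.elements]
        assert kinds == ["residue", "group", "residue"]
        assert ast.elements[1].quantifier == ONE

    def test_lookaround_flags(self):
        ast = parse_pattern("(?<=Neu5Aca3)Galb4(Fuca3)GlcNAc")
        assert ast.elements[0].lookaround == "behind"
        ast = parse_pattern("Galb4(?=GlcNAc)")
        assert ast.elements[-1].lookaround == "ahead"

    @pytest.mark.parametrize("bad", [
        "*Gal",                      # dangling quantifier
        "?",
        "Gal{3,2}",                  # min > max
        "Galb4(Fuca3GlcNAc",         # unbalanced
        "Galb4)Fuca3",
        "Gal(?<=Man)Glc",            # lookbehind not at start
        "(?=Man)Glc",                # lookahead not at end
        "(?=Man)",                   # nothing outside lookaround
        "(?=Gal)+",                  # quantified lookaround
        "Galb4(Fuca3)",              # branch with nothing to attach to
        "(Fuca3)(Galb4)+Glc",        # branch attached to a repeat
        "Gal((?=Man)Glcb3)Man",      # lookaround nested in a group
        "!.",                        # negated wildcard
        "",
        "galb4Glc",                  # residues start uppercase
    ])
    def test_rejects_malformed(self, bad):
        with pytest.raises(PatternParseError):
            parse_pattern(bad)

    @given(st.text(alphabet=string.printable, max_size=30))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_fuzz_total(self, text):
        """Arbitrary input either parses or raises a pattern parse error."""
        try:
            parse_pattern(text)
        except PatternParseError:
            pass


class TestInferLinkage:
    @pytest.mark.parametrize("mono, shorthand, expected", [
        ("Man", "a6", ["a1-6"]),
        ("Gal", "b3/4", ["b1-3", "b1-4"]),
        ("Neu5Ac", "a3", ["a2-3"]),
        ("Neu5Gc", "a6", ["a2-6"]),
        ("Kdn", "a3", ["a2-3"]),
        ("GlcNAc", "b4", ["b1-4"]),
    ])
    def test_donor_carbon_rule(self, mono, shorthand, expected):
        assert links(infer_linkage(mono, shorthand)) == expected

    def test_empty_shorthand_is_fully_unknown(self):
        assert links(infer_linkage("Gal", "")) == ["?1-?"]
        assert links(infer_linkage("Neu5Ac", "")) == ["?2-?"]

    def test_configurable_c2_list(self):
        assert links(infer_linkage("Sia", "a3", c2_prefixes=("Sia",))) == ["a2-3"]
        assert links(infer_linkage("Sia", "a3", c2_prefixes=())) == ["a1-3"]


class TestLinkageMatching:
    def test_unknown_matches_both_directions(self):
        unknown = LinkageLabel.from_token("?1-?")
        concrete = LinkageLabel.from_token("b1-4")
        assert linkage_matches(frozenset({unknown}), concrete)
        assert linkage_matches(frozenset({concrete}), unknown)

    def test_alternation_intersects(self):
        spec = infer_linkage("Gal", "b3/4")
        assert linkage_matches(spec, LinkageLabel.from_token("b1-4"))
        assert not linkage_matches(spec, LinkageLabel.from_token("b1-6"))
        assert linkage_matches(spec, LinkageLabel.from_token("b1-4/6"))

    def test_anomer_mismatch(self):
        spec = infer_linkage("Gal", "b4")
        assert not linkage_matches(spec, LinkageLabel.from_token("a1-4"))


class TestExpandQuantified:
    def test_optional_residue(self):
        (el,) = parse_pattern("Fuca3?").elements
        cc = expand_quantified(el)
        assert cc.allowed_counts == {0, 1}
        assert to_string(cc.substructure) == "Fuc"
        assert links(cc.attachment_linkage) == ["a1-3"]

    def test_lacnac_repeat_unit(self):
        (el,) = parse_pattern("(Galb4GlcNAcb3){1,3}").elements
        cc = expand_quantified(el)
        assert cc.allowed_counts == {1, 2, 3}
        assert to_string(cc.substructure) == "Galb1-4GlcNAc"
        assert links(cc.attachment_linkage) == ["b1-3"]

    def test_unbounded_needs_ceiling(self):
        (el,) = parse_pattern("Fuca3*").elements
        with pytest.raises(ValueError):
            expand_quantified(el)
        assert expand_quantified(el, ceiling=5).allowed_counts == set(range(6))

    def test_wildcard_unit_has_no_graph(self):
        (el,) = parse_pattern(".+").elements
        assert expand_quantified(el, ceiling=3).substructure is None
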