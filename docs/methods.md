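# Methods

## The glycan graph

A glycan is modelled as a rooted tree whose nodes alternate between
monosaccharides and glycosidic linkages; edges point toward the reducing
end (the root). Linkages are nodes rather than edge labels so that every
part of a match — including bonds — has an index that lookaround
exclusion and branch extraction can refer to. A glycan with *k* residues
always has 2*k*−1 nodes.

Node indices are the 0-based token positions of the *canonical*
serialization (left, non-reducing → right, reducing; parentheses do not
count). Canonicalization fixes the branch order at every branch point:
the branch with the longest residue path is written outside parentheses,
ties broken by the lowest acceptor carbon of the connecting linkage,
then lexicographically by child token and finally by the serialized
branch text. There is no community-wide convention for branch order in
IUPAC-condensed strings; this one is the package's own choice, made so
that serialization is deterministic and `to_string ∘ parse_iupac` is
idempotent — which the test suite asserts exactly. Parsing accepts both
the Unicode (α/β, en-dash) and ASCII dialects and any branch order;
matching is performed on the graph, so results never depend on how the
input string happened to be written.

Residue tokens are opaque strings: `GlcNAc6S` is a different token from
`GlcNAc` and the two do not match each other. Wildcards (`.`,
`Monosaccharide`) match any token.

## Matching semantics

The pattern AST is compiled into a linear program of items running
leafward → rootward: residue items (label spec, optional linkage spec,
bound side-branch programs) and repeat items (a chain unit plus a count
range). Lookbehind content is prepended, lookahead content appended,
with their nodes tagged so they can be excluded from the reported match.

Matching is an anchored recursive descent — an iterative tracing of
paths through the candidate embeddings of the individual elements.
Processing the program from its rootward end, each residue item
enumerates candidate residues (children of the residue matched by the
following item, reached through a linkage satisfying the item's linkage
spec; or any residue at the free rootward end), embeds its side
branches disjointly, and recurses leafward. Key rules, all of which the
brute-force oracle checks independently:

* the intervening linkage node between two consecutively matched
  residues is always part of the match and belongs to the leafward
  element (the one that carries the linkage spec);
* a trailing explicit linkage spec (`Mana6` at the pattern's rootward
  end) requires the bond to exist and includes its node, but not the
  parent residue;
* unknown linkage components (`?`) match anything, in both directions;
  acceptor alternation matches on non-empty carbon-set intersection;
* assignments are injective: one glycan node per pattern slot;
* unbounded quantifiers are capped per-glycan by the residue count (no
  repeat unit can occur more often);
* a branch pattern `(B)X` must embed as a side branch of the node
  matching `X`; extra, unmentioned branches of the glycan are ignored
  (negation is therefore positional, not an absence assertion).

**Greedy and lazy policies.** All valid matches are enumerated, then
deduplicated by node set. Greedy keeps the matches that are not strictly
contained in another valid match (count-maximal: no valid extension
exists); lazy keeps those that strictly contain no other valid match
(count-minimal). This set-based formulation handles multiple quantifiers
per pattern without an ordering convention, and directly yields the
dominance invariant that every lazy match is a subset of some greedy
match. Matches that realize the empty node set (patterns whose elements
all allow count 0) are not reported — unlike text regex, which reports
empty spans. Results are sorted by lowest node index, ties broken by
larger match first; the engine contains no randomness, so identical
inputs always produce identical output.

**Serialization of matches.** A match may legitimately end rootward on a
linkage node (a trailing or arm-attaching bond). Since a valid
IUPAC-condensed string must start and end on monosaccharides, such
dangling linkages are kept in the node list but omitted from the
serialized match string — this is the cut rule that makes extracted
branches (`Neu5Aca2-6Galb1-4GlcNAcb1-2Man` for an α1-6 arm, without the
trailing `a1-6`) re-parseable glycans.

## The brute-force oracle

`glyre.testkit.brute_force_match` recomputes matches by definition,
sharing only the parsers and the AST compatibility predicates with the
engine: it expands every quantifier into every concrete repeat-count
realization (bounded by the glycan's residue count), enumerates *every*
connected subtree of the glycan, and searches for a structure-preserving
bijection between concrete pattern slots and subtree nodes, trying all
child permutations. Exhaustive enumeration is exponential, so the oracle
refuses glycans above 12 residues. Engine/oracle agreement — exact, as
sets of node sets, per grammar feature, under both policies — is the
central acceptance property; the suite checks 500 seeded
(pattern, glycan) pairs per feature.

## The synthetic generator

`SyntheticGlycanSpec` draws random glycan trees: residues uniformly from
a nine-letter alphabet typical of mammalian glycans (Gal, Glc, Man,
GlcNAc, GalNAc, Fuc, Neu5Ac, Neu5Gc, Xyl); linkages from the common
anomer × acceptor-carbon pool {a,b} × {2,3,4,6}, with the donor carbon
set by the child residue (C2 for sialic acids, C1 otherwise) and
acceptor-carbon collisions on the same parent avoided. Defaults:
`max_residues=10` (the size range of typical N-/O-glycans), uniform
residue count in [1, max], `branch_prob=0.25` per attachment from the
third residue on (yielding a realistic mix of linear and branched
topologies — the empirical branching rate is tested against binomial
3σ bounds), `unknown_linkage_prob=0.05` for `?`-linkages as they occur
in mass-spectrometry-derived databases. The same spec and seed always
yield the identical string.

The generator emulates topology, not biosynthesis: it imposes no
pathway constraints, no core motifs, and no realistic residue/linkage
co-occurrence (a "Neu5Ac with children" can occur). Passing tests on
this corpus therefore certify the *matching semantics* on arbitrary
labeled trees — which is the claim — not recall on any particular real
glycome. The in-text structures (sialyl Lewis x, a disialylated
biantennary N-glycan, a 3×LacNAc chain) are used as fixed fixtures for
the biologically meaningful worked examples.

## Numerical and design choices

* **Test and acceptance problem sizes.** Oracle-equivalence sweeps use
  100 glycans × 5 patterns per feature (500 pairs, ≤12 residues); unit
  property tests use smaller corpora (20–50 glycans, ≤6–8 residues).
  These sizes give the oracle headroom while exercising every feature
  densely; all seeds are fixed in the tests.
* **Lookaround placement** is restricted to the pattern's ends
  (lookbehind leafward, lookahead rootward). Interior lookaround has no
  obvious single semantics on a tree; the restricted form covers the
  motivating use cases (terminal caps, core anchoring) unambiguously.
* **All matches are returned**, not only the first: branch extraction
  and motif counting need every occurrence. Overlapping matches are
  reported separately; deduplication is by node-set equality only.
* **Degenerate inputs.** A single-residue glycan is valid; an empty
  string, unbalanced parentheses, a dangling linkage, or a leafward cut
  through a linkage are errors that name the character offset. A
  pattern that matches nothing yields an empty result, never an error.
* **Quantified groups may nest** (a repeat unit may itself contain
  branches or quantifiers); each repetition realizes inner quantifiers
  independently, and the oracle mirrors this definitionally.

## Known limitations

* Only IUPAC-condensed input is parsed; WURCS, GlycoCT, Oxford and
  IUPAC-extended notations are out of scope.
* Wildcard repeats (`.*`) trace chains, not subtrees: an arm query such
  as `.*Mana6(?=core)` extracts linear arms in full but only the main
  path of an internally branched arm.
* Residue alternation (`Gal|GalNAc`) and top-level pattern alternation
  are not part of the grammar; linkage alternation (`b3/4`) is.
* Exhaustive matching of pathological patterns (many unbounded
  wildcard quantifiers on large glycans) can be slow; practical motif
  queries are fast.
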