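# glyre — regular expressions for branched glycan structures

Glycans are branched polymers of monosaccharides, and the biology often
lives in *motifs*: short sequence patterns like sialyl Lewis x,
Neu5Acα2-3Galβ1-4(Fucα1-3)GlcNAc, whose meaning depends on where in the
larger structure they sit (terminal vs internal, α1-3 arm vs α1-6 arm of
an N-glycan). Plain-text regular expressions cannot interrogate such
structures reliably — the same tree can be written as many different
strings — so `glyre` implements a regular-expression dialect that operates
on the *glycan graph* instead.

It is aimed at glycobiologists and glycoinformaticians who want to

* find and extract motifs of arbitrary complexity, with wildcards,
  linkage ambiguity, negation, quantifiers (greedy or lazy) and
  lookahead/lookbehind;
* pull designated sequence stretches (e.g. the α1-6 branch of N-glycans)
  out of many structures at once;
* build glycan × motif count matrices for downstream enrichment or
  differential-expression statistics.

## How it works

An IUPAC-condensed string is parsed into a rooted tree in which both
monosaccharides and linkages are indexable nodes (a glycan with *k*
residues has 2*k*−1 nodes), the root being the reducing end. A pattern is
chunked into homogeneous elements: plain segments are located by
label-constrained subgraph isomorphism; quantified segments become
dictionaries of *(substructure: allowed counts)*; then a path is traced
through the candidate embeddings so that every count constraint holds and
the match is a **connected** portion of the graph. Lookahead/lookbehind
context must be present but its node indices are excluded from the
reported match. Matching is greedy by default (count-maximal); a `?`
modifier (`+?`, `*?`, ...) requests lazy (count-minimal) matching.

Pattern syntax in brief (see `docs/grammar.md` for the EBNF):
`Mana6` (linkage shorthand; donor carbon inferred, C2 for sialic acids),
`Galb3/4` (linkage alternation), `.` / `Monosaccharide` (wildcard),
`!Fuc` (negation), `(Fuca3)GlcNAc` (branch), `(Galb4GlcNAcb3)+`
(repeats), `?` `*` `+` `{n}` `{n,m}` `{n,}` (quantifiers),
`(?<=...)` / `(?=...)` (lookaround).

## Worked example

```python
>>> from glyre import get_match
>>> slex = "Neu5Acα2-3Galβ1-4(Fucα1-3)GlcNAc"   # sialyl Lewis x

>>> get_match("Fuca3GlcNAc", slex).matches
((4, 5, 6),)
>>> get_match("Fuca3GlcNAc", slex).match_strings
('Fuca1-3GlcNAc',)

>>> get_match("(?<=Neu5Aca3)Galb4(Fuca3)GlcNAc", slex).matches
((2, 3, 4, 5, 6),)
```

The first query finds exactly one occurrence of fucosylated GlcNAc: node
indices 4, 5, 6 are Fuc, the α1-3 linkage and GlcNAc in the canonical
serialization `Neu5Aca2-3Galb1-4(Fuca1-3)GlcNAc` (indices count tokens
left to right from 0). The lookbehind variant demands the Neu5Acα2-3 cap
but excludes its two nodes (0, 1) from the match.

Branch extraction on a biantennary N-glycan:

```python
>>> from glyre import extract_branch, alpha16_arm_query
>>> biant = ("Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-6"
...          "(Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-3)"
...          "Manb1-4GlcNAcb1-4GlcNAc")
>>> extract_branch(biant, alpha16_arm_query())
['Neu5Aca2-6Galb1-4GlcNAcb1-2Man']
```

The query `.*Mana6(?=Manb4GlcNAcb4GlcNAc)` anchors on the invariant
N-glycan core via lookahead and returns everything on the α1-6 arm as a
valid glycan string of its own.

The same operations are available from the shell:

```sh
glyre match  -p "Fuca3GlcNAc" -g glycans.txt
glyre extract -q queries.tsv -g glycans.txt -o arms.tsv
glyre count  -p patterns.tsv -g glycans.txt -o counts.tsv
glyre simulate --n 100 --seed 7 -o glycans.txt
glyre explain "(?<=Neu5Aca3)Galb4(Fuca3)GlcNAc"
```

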