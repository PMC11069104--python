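# The glyre pattern grammar

Patterns read in the same direction as IUPAC-condensed glycan strings:
non-reducing end (leaves) first, reducing end (root) last. Whitespace is
insignificant; Unicode α/β and en/em dashes are normalized to `a`/`b`
and `-` before tokenization.

## EBNF

```ebnf
pattern     = [ lookbehind ] , element , { element } , [ lookahead ] ;
lookbehind  = "(?<=" , element , { element } , ")" ;
lookahead   = "(?=" , element , { element } , ")" ;

element     = residue | branch | repeat ;
residue     = [ "!" ] , token , [ linkage ] , [ quantifier ] ;
branch      = "(" , element , { element } , ")" ;          (* unquantified *)
repeat      = "(" , element , { element } , ")" , quantifier ;
token       = named | "." | "Monosaccharide" ;             (* "." = wildcard *)
named       = upper , { letter | digit } ;

linkage     = anomer , [ donor , "-" ] , acceptor , { "/" , digit } ;
anomer      = "a" | "b" | "?" ;
donor       = "1" | "2" | "?" ;
acceptor    = digit | "?" ;    (* "?" acceptor only in the full "?1-?" form *)

quantifier  = ( "?" | "*" | "+" | count ) , [ "?" ] ;      (* trailing "?" = lazy *)
count       = "{" , integer , [ "," , [ integer ] ] , "}" ;
```

## Semantics and disambiguation rules

* **Adjacency is attachment.** Consecutive elements are child → parent:
  in `Fuca3GlcNAc` the Fuc is attached to GlcNAc through a linkage
  matching `a1-3`. The matched linkage node belongs to the element that
  carries the spec (here Fuc) and is part of the match.
* **Linkage inference.** A shorthand linkage (`a6`, `b3/4`) omits the
  donor carbon; it is inferred from the monosaccharide — C2 for ulosonic
  acids (names starting with Neu, Kdn, Kdo, Leg, Pse, Aci, Sia), C1
  otherwise. For wildcards and negated residues the donor stays unknown.
  `Gal` with no linkage at the end of a pattern matches regardless of how
  (or whether) the Gal is attached; a trailing explicit linkage
  (`Mana6`) *requires* the bond and includes its node in the match.
* **Named residues need a linkage between them.** Elements carry no
  separator, so `GalGlcNAc` would lex as a single opaque token. Write
  `Galb4GlcNAc`, or `Gal?1-?GlcNAc` for "any linkage", or use `.`.
* **Parenthesis overloading.** `( ... )` directly before a residue is a
  glycan *branch* attached to that residue; `( ... )` followed by a
  quantifier is a *repeat unit* along the chain; `(?=...)` / `(?<=...)`
  are lookaround. `(X){1}` is simply the chain `X`.
* **`?` overloading.** After a residue/group it is the {0,1} quantifier;
  after another quantifier it requests lazy matching; inside a linkage it
  marks an unknown component. `Gal?4` is a linkage (`?-4`), `Gal?` an
  optional Gal, `Gal??` a lazy-optional Gal; an unknown acceptor carbon
  requires the full form `?1-?`.
* **Negation is positional.** `!Fuc` matches exactly one residue whose
  token is not Fuc at that position; it does not assert absence of Fuc
  elsewhere in the glycan.
* **Lookaround placement.** Lookbehind may only open the pattern
  (leafward context), lookahead only close it (rootward context); both
  are matched but their node indices are excluded from results.
* **Unknown components match both ways.** A `?` anomer/carbon in either
  the pattern or the glycan matches anything; acceptor alternation
  (`3/4` in a pattern, `a1-3/6` in a glycan) matches when the carbon
  sets intersect.
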