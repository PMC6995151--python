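# tetraquad

Identification and topological classification of **tetrads** and
**quadruplexes** in nucleic-acid 3D structures.

A tetrad (or quartet) is a planar arrangement of four nucleotides in
which each base pairs with its two neighbours — along its Watson–Crick
edge with one, along its Hoogsteen edge with the other — closing a
4-cycle of base pairs. When two or more tetrads stack (~3.3 Å apart),
they form a quadruplex, a motif found in telomeres and transcriptional
regulatory regions and increasingly targeted in biomedicine. Most
computational work has concentrated on canonical all-guanine
quadruplexes (G4s); `tetraquad` classifies canonical *and* non-canonical
motifs purely from the **topology of their secondary structure**, using
the ONZ taxonomy.

## The classification

Let a tetrad T have residues A, B, C, D with pairs (A,B), (B,C), (C,D),
(D,A), where in each pair the first residue binds along its Watson–Crick
edge and the second along its Hoogsteen (or Sugar) edge, and A is the
5′-most of the four. The 5′→3′ arrangement of the residues fixes the
class:

| 5′ → 3′ order | class | | 5′ → 3′ order | class |
|---|---|---|---|---|
| A–B–C–D | **O+** | | A–C–D–B | **N−** |
| A–D–C–B | **O−** | | A–C–B–D | **Z+** |
| A–B–D–C | **N+** | | A–D–B–C | **Z−** |

The letters name the O-, N- and Z-shaped tracks the pairings trace in a
secondary-structure diagram; the sign records the cycle direction
relative to the strand direction. The six permutations of {B, C, D} are
exhaustive, so every oriented tetrad receives exactly one class.

Quadruplexes combine (i) the common tetrad letter — O/N/Z, or **M**
(mixed) when letters differ, or **R** when some tetrad is unclassified;
(ii) the strand progression read from the four N-tracts — parallel
(**p**) when all four tracts run the same way, antiparallel (**a**) for
a 2/2 split, hybrid (**h**) for 3/1; and (iii) a subtype: **+** / **−**
when all tetrad signs agree, **\*** for a mixture. Example classes:
`Op+`, `Oa*`, `Mh*`.

For bi- and tetramolecular motifs the 5′→3′ order of strands is itself
ambiguous. `tetraquad` therefore examines all permutations of the
participating chains and commits the one maximizing the number of
O-class tetrads (O-type tetrads dominate in unimolecular structures);
`--no-reorder` disables this, leaving multi-strand tetrads unclassified.

## Usage

```bash
tetraquad --pdb structure.cif                 # internal annotation
tetraquad --dssr-json structure.json          # precomputed annotation
tetraquad --dssr-json s.json --stacking-mismatch 0 --strict --complete-2d
```

Flags: `--stacking-mismatch {0,1,2}` (default 2) tolerates unstacked
residue columns between consecutive tetrads; `--relaxed-stem-definition`
joins sequentially neighbouring tetrads regardless of stacking;
`--strict` traverses only cis Watson-Crick/Hoogsteen pairs;
`--no-reorder` keeps the input chain order; `--complete-2d` also draws
canonical pairs outside the motifs; `--output`, `--model`, `--config`
(TOML palette), `--annotator {internal,json}`.

Each run writes a text report, a JSON report and an SVG arc diagram in
which arcs are colored by tetrad class (O blue, N green, Z orange; dark
for +, light for −; grey for unclassified; black for canonical pairs
outside the motif).

### Worked example

A synthetic three-tetrad quadruplex with one reversed tetrad
(generated by the bundled fixture module, exported as annotator JSON):

```bash
$ python -c "
import json
from tetraquad import fixtures as fx
g, _ = fx.make_quadruplex_graph('O', 'p', '*', n_tetrads=3, seed=42)
open('example.json', 'w').write(json.dumps(fx.to_dssr_json(g)))"
$ tetraquad --dssr-json example.json --output out
```

prints to `out/example.txt`:

```
Chain order: A
Quadruplex #1: Op* (3 tetrads)
  Tetrad 1: O+ A.G3 A.G8 A.G11 A.G14
  Tetrad 2: O- A.G4 A.G15 A.G12 A.G9
  Tetrad 3: O+ A.G5 A.G10 A.G13 A.G16
  Tract A: A.G3 A.G4 A.G5
  Tract B: A.G8 A.G9 A.G10
  Tract C: A.G11 A.G12 A.G13
  Tract D: A.G14 A.G15 A.G16
Dot-bracket:
  AAGGGGCGGGGGGGGG
  ..([[..)(][)(]])
  ..(([..[)(][))]]
```

Reading: one quadruplex of three stacked guanine tetrads was found. All
tetrads are O-type and all four tracts run 5′→3′, so the motif is
parallel (`Op`); the middle tetrad's pair cycle runs against the strand
direction (`O-`), so the signs mix and the subtype is `*`. The two
bracket lines split each tetrad's 4-cycle — (A,B) and (C,D) pairs on the
first line, (B,C) and (D,A) on the second — because a 4-cycle cannot be
written on a single properly nested line; parsing both lines recovers
exactly the twelve tetrad pairs.

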