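# Methods

This note documents the models, procedures and numerical choices behind
`tetraquad`, and what the synthetic test fixtures do and do not show.

## Annotation graphs

All classification operates on an *annotation graph*: residues ordered
5′→3′ within chains, Leontis–Westhof-annotated base pairs, and
base-stacking contacts. Each base pair is stored once and queried
symmetrically: asking for the pair from either endpoint returns that
residue's own interacting edge (Watson–Crick, Hoogsteen or Sugar), with
the shared cis/trans orientation. `global_index` — the residue's rank in
the committed chain ordering — is the only geometric-free quantity the
ONZ rules consult, so classification is invariant under any
order-preserving renumbering (property-tested).

Graphs are ingested from annotator-style JSON (`read_dssr_json`: `nts`,
`pairs` with `LW` strings, `stacks` records whose consecutive members
become contacts; unknown LW codes such as `c--` keep the pair with
unknown edges), from the package's own JSON dialect (exact round trip),
or from PDB/mmCIF coordinates via the internal annotator. Multi-model
(NMR) files default to model 1, the common annotator convention; a
`--model` flag selects others. Modified nucleotides map to a parent base
through a bundled table (e.g. BRU → T); unmapped residues keep base `?`
and may still join tetrads, since the default mode deliberately admits
non-canonical chemistry.

## Geometric annotation (fallback annotator)

When only coordinates are given, base pairs are detected from
hydrogen-bond geometry: at least 2 polar heavy-atom contacts within
3.5 Å, each contact vector within 60° of both base planes (this rejects
the short vertical N/O distances between stacked bases). Each residue's
edge is the Leontis–Westhof edge whose atoms participate most in the
contacts (ties resolve WC > Hoogsteen > Sugar); cis/trans comes from the
glycosidic torsion C1′–N(gly)–N(gly)′–C1′ (|τ| ≤ 90° ⇒ cis). Stacking
requires ring-centroid distance ≤ 4.5 Å, inter-plane angle ≤ 30°, and
nonzero overlap of the ring polygons projected onto the mean plane.
All thresholds live on `AnnotationConfig`; the defaults follow common
annotation practice and are deliberately permissive — tetrad finding,
not pair detection, decides admissibility. Parity with any particular
external annotator on arbitrary PDB entries is a best-effort goal, not
an invariant.

## Tetrad finding

Tetrads are vertex-disjoint 4-cycles in the pair graph. In strict mode
only cis WC/Hoogsteen pairs are traversable; by default any pair is,
which admits tetrads linked by pairs of different types (the flip side
is a small risk of spurious 4-cycles in densely paired regions — the
disjoint-selection preference for cis WC/H pairs mitigates this). When
candidate cycles overlap, an exact branch-and-bound search selects the
subset maximizing (cardinality, total cis-WC/H pairs), breaking
remaining ties by lexicographically smallest 5′-most indices, residue
sets and edge lists — the last two exist purely to make fully tied
selections deterministic. Beyond 40 candidate cycles the search turns
greedy with a logged warning (unreachable for realistic structures).
Equivalence with exhaustive enumeration is asserted on 200 seeded random
graphs of ≤ 12 residues.

Each cycle is oriented canonically: A is the 5′-most residue and B the
neighbour A binds along its own Watson–Crick edge; if A's edges toward
both neighbours are symmetric or unknown, B is the neighbour with the
smaller index. The fallback makes orientation total (hence
classification total in non-strict mode) and is a pure function of the
cycle's pairs and indices.

## ONZ and ONZM classification

The six ordering rules (README table) are implemented as a lookup on
the permutation of {B, C, D} sorted by index. Enumeration confirms the
six permutations map bijectively onto the six classes, and that swapping
B and D (reversing the cycle) maps O+↔O−, N+↔Z−, N−↔Z+.

Quadruplex letter, direction and sign are computed independently:
letter from the tetrad letters (M when mixed, R when any tetrad is
unclassified), direction from the monotonicity of tract indices along
the stack (4/0 parallel, 2/2 antiparallel, 3/1 hybrid), sign from the
tetrad signs (+/−/\*). M-class quadruplexes get directions the same way
as regular ones. A non-monotone tract leaves direction `?` with a
warning rather than failing. A two-tetrad quadruplex always has
well-defined directions. Classification is invariant under reading the
stack bottom-up, which flips all tract directions simultaneously.

## Quadruplex assembly

Two tetrads are stacked when a one-to-one matching of their residues
covers ≥ (4 − mismatch) pairs present in the stacking-contact set, with
mismatch ∈ {0, 1, 2} (default 2). The optimal matching is computed by
exhaustive 4! assignment — exact and cheap, avoiding greedy-matching
ambiguity; among equal-score assignments the lexicographically first is
kept, which prefers slot-aligned matchings when stacking cannot
distinguish them. Agreement with a Hungarian-algorithm solver is
asserted on 200 seeded trials.

Connected components of the stacking relation with ≥ 2 tetrads become
quadruplexes; singletons are lone tetrads. Under the relaxed stem
definition, components additionally join through *sequence adjacency*,
defined as: on every chain shared by the two tetrads, the combined
residue span contains no residue of a third tetrad. Components are
ordered along a stacking path starting from the tetrad holding the
5′-most residue (greedy by stacking score, then 5′ position; a
component with no full path falls back to 5′ ordering with a warning).
Tract columns chain the consecutive matchings from the first tetrad's
(A, B, C, D).

**N4-helix.** The term (a coaxial stack extending beyond one
quadruplex's four tracts) has no published operational definition, so
the package uses its own, documented one: a component splits into
quadruplex segments wherever the matching between consecutive tetrads
pairs residues from different chains (a tract break); a component with
more than one segment is reported as an N4-helix, and ONZM
classification applies per segment. Limitation: two quadruplexes from
the *same* chain stacked coaxially are not split, because every tract
break there is chain-internal.

## Strand reordering

ONZ classes of multi-strand tetrads depend on the processing order of
chains. With reordering enabled (the default), all permutations of the
chains participating in tetrads are examined (non-participating chains
keep their relative order after them); for each permutation every tetrad
is re-oriented and re-classified, and the permutation maximizing
(#O-class tetrads, then #N-class, then lexicographically earliest chain
order) is committed. The objective deliberately ignores tetrad signs.
Since the identity order is among the permutations, reordering can never
decrease the number of O tetrads — property-tested on 100 seeded
multichain fixtures. Beyond 8 participating chains (40 320
permutations) the exhaustive search is refused and the input order kept,
with a warning. With `--no-reorder`, multi-strand tetrads stay
unclassified, their arcs render grey, and their quadruplexes fall into
the R class.

## Dot-bracket and arc diagram

A tetrad's 4-cycle cannot be written on one properly nested bracket
line, so the encoding uses two lines under one sequence line: pairs
(A,B), (C,D) on line 1 and (B,C), (D,A) on line 2. The split is a fixed
convention of this package (any fixed split with documented parse-back
is unambiguous; the original tool's exact split convention is not
published, so this is a dialect). Within each line, crossing pairs get
distinct bracket levels — `()`, `[]`, `{}`, `<>`, then `Aa`…`Zz` — by
greedy interval coloring in 5′ order; 56 levels would be needed before
failure, which is practically unreachable. Chain breaks render as `-`
in all three lines. Parse-back recovering the exact emitted pair set is
asserted on every fixture.

Arc diagrams are plain SVG with residues on a horizontal axis in the
committed chain order. Default colors: O+ `#003366`, O− `#99CCFF`,
N+ `#006400`, N− `#90EE90`, Z+ `#CC6600`, Z− `#FFCC66`, grey `#808080`
for unclassified, black `#000000` for canonical pairs outside the motifs
(drawn only with `--complete-2d`). The published scheme specifies hues
and light/dark shading; the exact hex values are this package's
defaults and are overridable through a TOML `[palette]` table.
Rendering is deterministic (no timestamps, sorted element order), so
identical inputs produce byte-identical files.

## Synthetic fixtures: what they show and what they do not

Graph-level generators lay residues and cis WC/H pair cycles out so a
requested class *must* result: single tetrads for all six classes on 1,
2 or 4 chains (class guaranteed under the emitted chain order), and
quadruplexes for every (letter ∈ {O,N,Z,M}) × (p/a/h) × (+/−/\*)
combination via per-tetrad cycle choices over four tract blocks.
Adversarial multichain variants emit a scrambled chain order whose
reordering outcome was hand-enumerated and frozen as ground truth; with
four single-residue strands only O targets exist, because some
permutation always realizes an O class, so an O-maximizing optimizer can
never commit N or Z there. The eight-strand "octamer" fixture emulates
the published DNA/RNA-hybrid double-quadruplex narrative: ten tetrads
unclassifiable in the input order, and after reordering two 5-tetrad
Op\* quadruplexes with 4 O+/1 O− and 3 O+/2 O− compositions.

Coordinate fixtures place idealized base geometry (bundled
chemical-component library) rigidly: a cWH G·G pair built by aligning
one G's Hoogsteen acceptors to the other's Watson–Crick donors at
2.85 Å; a canonical G·C pair (flipped normals, as in an antiparallel
duplex); stacked/coplanar/tilted guanine two-residue probes; and a
closed G-tetrad made of exact 90° rotations about a least-squares
center. These validate the geometric annotator's thresholds and
invariances, not its fidelity on experimental coordinates: real
structures have propeller twist, buckled tetrads, sugars and backbones
the fixtures idealize away. Passing the suite therefore demonstrates
correctness of the *classification logic* and of the annotator's stated
geometric criteria — not annotator parity with external tools on
arbitrary PDB entries.

Problem sizes used by the test suite and the acceptance script — random
graphs of ≤ 12 residues (200 trials), 100 multichain reordering cases,
the 55-fixture class grid, and the 40-residue octamer — were chosen as
the smallest sizes that exercise every code path exhaustively
(brute-force oracles are exact at these sizes); the whole-PDB census
scale analysis is out of scope for this package's test surface.
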