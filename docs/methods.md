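# Methods

## Scope and model

`orbitcount` computes exact induced-subgraph orbit signatures for simple
undirected graphs: for every vertex, the number of times it occupies each
of the 73 automorphism orbits of the 30 connected graphs on 2–5 nodes
(and, per edge, each of the 69 edge orbits).  The host graph may be
disconnected and may contain isolated vertices; multi-edges, self-loops,
weights and directions are out of scope, as is any k ≥ 6 counting.  All
quantities are integers throughout; no floating point enters any code
path.

## The graphlet atlas and its numbering

The atlas enumerates all connected 2–5-node graphs and assigns them the
graphlet and orbit numbering that graphlet-degree-vector tooling has
standardised on, so count matrices are column-compatible with existing
pipelines.  That numbering is conventional rather than rule-derived, so
the adjacency lists are embedded as a fixture table.  The table was
reconstructed from the anchors the derivation itself fixes and is
validated by tests at several levels:

* cardinalities (1, 2, 6, 21 graphlets; 73 orbits) against a brute-force
  isomorphism census;
* direct anchors: G1 = 3-path, G5 = 4-cycle with single orbit 8,
  G7 = diamond with orbits {12, 13}, the 5-path orbits 15/16/17,
  m(16) = 9, m(59) = 24, m(70) = 28;
* structural anchors implied by the published equations: the orbit-59
  relation forces G24 (diamond plus an apex on a degree-2/degree-3 pair),
  G26 = K5 less two adjacent edges, G27 = K5 less two disjoint edges,
  G28 = K5 less an edge, with the marked orbits on the low-degree
  classes; the o50 + o55 relation forces G20 = K2,3 and G22 = the
  three-page book.  The equation builder reproduces both relations
  coefficient-for-coefficient, which pins the ids 59, 65, 68, 70, 49,
  50, 54 and 55 jointly.

Within a graphlet, orbits are ordered by an ascending degree-refinement
key (degree, then local triangle count, then the sorted neighbour keys).
This rule agrees with every published anchor above; where no anchor
exists it is this package's own deterministic convention.  Four pairs of
same-size graphlets with equal edge and orbit counts (the bull/cricket
pair, the two 5-node tadpoles, the two diamond-plus-pendant forms, and
K4-plus-pendant versus K2,3-plus-edge) are not distinguishable from any
anchor available to us; their relative order in the fixture follows the
conventional chart as best we can reconstruct it, and every internal
computation is independent of that choice.  Edge orbits have no published
numbering at all; they are numbered graphlet-by-graphlet in atlas order
and, within a graphlet, by the sorted pair of endpoint node-orbit ids.

Identification of an induced subgraph uses invariant keys instead of
canonical labelling: a connected graph on ≤ 5 nodes is determined by
(node count, degree sequence, triangle count), a vertex's orbit by
(degree, triangles, sorted neighbour (degree, triangle) pairs), and an
edge orbit by the sorted endpoint keys.  Completeness of these invariants
over the whole atlas is asserted at import and exercised by
label-invariance property tests; it is a property of graphs this small,
not of graphs in general.

## Equation derivation

For each non-clique orbit the builder picks the representative x (the
smallest canonical label in the orbit), selects the removable node y by
the layer rule — lowest-degree vertex of the farthest BFS layer,
falling back to the previous layer, ties broken by smallest label — and
requires (i) d(y) ≤ k−2, (ii) connectivity after removal, (iii) a
connected neighbourhood when d(y) = k−2.  The implementation scans the
layer's candidates in (degree, label) order and takes the first valid
one; whenever the minimal-degree candidate fails the conditions the whole
farthest layer fails (this is the one special case of the existence
proof), so the scan is equivalent to the textbook rule while also
handling the edge-orbit variant, where the second endpoint of the marked
edge is excluded from candidacy.  Complete graphlets signal
direct enumeration; the 4-cycle signals its special case, and its
equation is generated by the same machinery with y forced to a neighbour
of x.

Extension sets are computed by definition: every subset E of the reduced
graphlet whose one-vertex attachment is isomorphic to the target graphlet
with the marked vertex (edge) in the target orbit.  Coefficients f_p are
likewise counted by definition over (z, E) pairs.  The test suite
re-derives both with networkx isomorphism backends, and verifies
constructively that each extension rebuilds its target.  Systems are
built once per (k, mode) and cached; they are host-independent.

An important subtlety, worth recording because a naive re-implementation
gets it wrong: when counting how often a denser graphlet G* is reached,
only removals z for which the *marked element lands in the reduced
graphlet's marked orbit* participate.  Dropping that constraint inflates,
e.g., the 4-cycle relation from 2·o8 + 2·o12 to 3·o8 + 2·o12 + o13,
because the 4-cycle is vertex-transitive and accepts rebuilds from the
wrong path-end role.

## Counting engine

The engine follows the four-step layout: common-neighbour tables (for
k = 4, degrees plus adjacent pairs — O(n·d); for k = 5 all co-neighboured
pairs plus connected triples — O(n·d²)); one-pass clique enumeration by
ordered growth inside successive common neighbourhoods; a single
Wernicke-style enumeration of connected (k−1)-sets whose occurrences are
identified by the invariant keys, embedded by a ≤ (k−2)!-permutation
search, and distributed into every touched vertex's (edge's) right-hand
sides; and per-row integer back-substitution ordered by decreasing
graphlet edge count.  Exact divisibility and nonnegativity of every
solved count act as correctness witnesses: a violation raises
`IntegrityError` instead of producing a wrong matrix.  The 4-cycle
right-hand side (node and edge mode, k = 4) is evaluated from a per-focal-
vertex two-hop scratch table of c(x, x₂) values, reused across vertices.

Vertex sets are represented as Python integer bitmasks; adjacency tests,
neighbourhood intersections and popcounts are single machine-assisted
operations, which keeps the pure-Python engine fast enough that the full
validation grid (below) runs in well under a minute per mode.

## Synthetic data

The generators produce the deterministic fixtures (path, cycle, star,
clique, barbell — two near-equal cliques joined by one bridge edge) and
Erdős–Rényi G(n, p) graphs drawn pair-by-pair with `random.Random`, whose
Mersenne-Twister stream is stable across platforms, so a (family, n, p,
seed) tuple names one graph forever.  The validation grid uses
n ∈ {15, 25, 40} and p ∈ {0.05, 0.1, 0.2, 0.3} with five seeds per cell:
spanning sparse to moderately dense regimes while keeping the brute-force
oracle exact and affordable.  These random graphs probe correctness, not
realism: they lack the heavy-tailed degree distributions and clustering
of real interaction networks, so passing the grid certifies the
arithmetic of the method, and says nothing about biological
interpretation of the signatures.  Correctness on structured extremes is
covered separately by the closed-form hosts (cliques, cycles, paths,
stars, barbells).

## Oracle

The brute-force oracle enumerates every connected induced k-subset once
by anchored growth (checked against filtering all C(n, k) subsets up to
n = 12), classifies each by the atlas keys, and tallies node orbits, edge
orbits and graphlet totals.  It shares nothing with the equation path —
no common-neighbour tables, no cliques, no solve — so exact agreement
between the two is a genuine two-route check.  It refuses instances with
C(n, k) beyond a cap (default 10⁷, roughly n ≈ 60 at k = 5) since it is a
test instrument, not a production path.  As a third route, 3- and 4-node
graphlet totals are also checked against igraph's motif census — an
unrelated C implementation — in the test suite.

## Known limitations

* The atlas is scoped to k ≤ 5.  The equation builder itself is generic,
  but nothing above k = 5 is validated, and the counting engine hard-codes
  table shapes for k ∈ {4, 5}.
* The four unanchored graphlet-id pairs noted above cannot be certified
  against external tooling from within this repository; if a
  column-exchange discrepancy with another implementation is ever
  observed, it will be one of those pairs (or an orbit tie inside one
  graphlet) and is a fixture-table edit away.
* Expected-time behaviour on random graphs is not benchmarked here;
  complexity statements are the structural bounds above.
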