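# orbitcount

Exact graphlet node- and edge-orbit counting for sparse undirected
networks, via an automatically derived triangular system of integer
equations instead of exhaustive subgraph enumeration.

## The problem

*Graphlets* are the small connected induced subgraphs of a network — on
2–5 nodes there are 30 of them up to isomorphism.  The positions a vertex
can occupy inside a graphlet split into *orbits* under the graphlet's
automorphism group: the end of a 4-path is a different role than its
middle.  Over all 2–5-node graphlets there are 73 node orbits.  The vector
of per-vertex orbit counts (the *graphlet degree vector*) is a local
topology signature widely used in bioinformatics, e.g. to compare
protein–protein interaction networks or to predict protein function from
a node's wiring pattern; the analogous per-edge signature uses edge
orbits.  Counting is over *induced* occurrences, so every count is an
exact nonnegative integer.

## The method

Direct enumeration of k-node subgraphs costs O(n·d^(k−1)) on a graph with
n vertices and maximum degree d.  This package instead relates the orbit
counts of a fixed vertex x through linear equations: for each orbit O_i of
a k-node graphlet G_a, remove a carefully chosen node y so that
G′ = G_a∖{y} stays connected, and observe that every occurrence of G_a at
x arises by re-attaching a vertex to an occurrence of G′ at x along an
*extension set* E ⊂ V(G′).  Counting candidate re-attachment vertices with
precomputed common-neighbour counts c(S) gives

    o_i + Σ_p f_p·o_p  =  Σ_{G′ at x} Σ_{E∈ℰ} ( c(E in H) − c(E in G′) ),

where the left-hand orbits p all belong to graphlets with strictly more
edges and the integer coefficients f_p are host-independent symmetry
counts (e.g. the published relation
o59 + 4·o65 + 2·o68 + 6·o70 = Σ (c(x1,x3)−1) + (c(x2,x3)−1) over diamonds
at x).  The removable node y — the lowest-degree vertex of the farthest
BFS layer from x, with a fallback layer in one special case — always
satisfies d(y) ≤ k−2, keeps G′ connected, and has a connected neighbourhood
when d(y) = k−2.  Such a y exists for every graphlet except complete
graphs, whose orbit is counted by direct clique enumeration, and the
4-cycle, which gets a special equation (2·o8 + 2·o12) evaluated with O(n)
scratch space.  The system is triangular in graphlet edge count and is
solved per vertex by exact integer back-substitution; a division that
leaves a remainder is reported as an error, never rounded.  Total cost is
O(n·d^(k−2)) plus clique enumeration, with O(n·d^(k−3)) table space.

The same construction runs for *edge* orbits by fixing an edge
(x_a, x_b) and forbidding y = x_b.  A brute-force enumeration oracle is
included and the test suite checks the engine against it exactly.

## Worked example

Count 4-node orbits on a bowtie (two triangles sharing vertex 2) with a
pendant vertex 5 attached to vertex 4:

```python
from orbitcount import HostGraph, count_node_orbits

h = HostGraph(6, [(0,1), (0,2), (1,2), (2,3), (2,4), (3,4), (4,5)])
for v, row in enumerate(count_node_orbits(h, 4).rows):
    print(v, row)
```

prints

```
0 (2, 2, 0, 1, 1, 0, 0, 0, 0, 1, 2, 0, 0, 0, 0)
1 (2, 2, 0, 1, 1, 0, 0, 0, 0, 1, 2, 0, 0, 0, 0)
2 (4, 1, 4, 2, 0, 2, 0, 0, 0, 0, 1, 4, 0, 0, 0)
3 (2, 3, 0, 1, 0, 0, 0, 0, 0, 1, 3, 0, 0, 0, 0)
4 (3, 2, 2, 1, 0, 2, 0, 0, 0, 1, 2, 1, 0, 0, 0)
5 (1, 2, 0, 0, 2, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0)
```

Columns are orbits 0–14.  Column 0 is the degree; column 3 counts
triangles (vertex 2 sits in both, everyone else in one, vertex 5 in
none); column 11 counts appearances as the hub of a "paw" (triangle plus
pendant) — the bowtie centre is that hub four times, once per choice of
triangle and attached extra vertex.  Column 8 (the 4-cycle) is zero
everywhere: the graph has no induced 4-cycle.

The same counts from the shell, plus a 5-node edge-orbit run:

```
orbitcount generate erdos_renyi 100 er.txt --p 0.05 --seed 7
orbitcount node 5 er.txt node_counts.txt
orbitcount edge 5 er.txt edge_counts.txt --dump-equations system.json
```

`node_counts.txt` holds one row of 73 integers per vertex;
`edge_counts.txt` one row of 69 integers per input edge; `system.json`
the derived equation system.  `--oracle` switches to brute-force
enumeration for cross-validation on small graphs.

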