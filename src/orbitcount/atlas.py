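"""Atlas of small connected graphs (graphlets) and their automorphism orbits.

The atlas covers every connected simple graph on 2-5 nodes: 30 graphlets
(1 + 2 + 6 + 21) carrying 73 node orbits in total.  Graphlet ids G0-G29 and
node-orbit ids O0-O72 follow the numbering that is standard in the
graphlet-degree-vector literature, so count matrices produced by this
package line up column-for-column with existing graphlet tooling.  The
numbering is not derivable from a closed rule, so the graphlet adjacency
lists are embedded below as a fixture table; the orbit order within a
graphlet is reproduced by a deterministic degree-refinement rule (see
``_vertex_refinement_key``) that agrees with the published order on every
anchor we can pin (path, cycle, paw, diamond orbits, m(16)=9, m(59)=24,
m(70)=28, the O50/O55 and O59/O65/O68/O70 equation structure).

Edge orbits (automorphism classes of edges) have no widely published
numbering; they are numbered here deterministically: graphlets in atlas
order, and within a graphlet by the sorted pair of node-orbit ids of the
edge endpoints.

All per-graphlet data (automorphism groups, orbit partitions,
identification keys) is derived from the fixture table at import time and
cross-checked by assertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Sequence, TextIO

from .errors import IdentificationError, UnsupportedSizeError

__all__ = [
    "Graphlet",
    "Orbit",
    "EdgeOrbit",
    "GRAPHLET_COUNT",
    "NODE_ORBIT_COUNT",
    "EDGE_ORBIT_COUNT",
    "enumerate_graphlets",
    "node_orbits",
    "edge_orbits",
    "identify",
    "identify_edge",
    "graphlet_of_orbit",
    "graphlet_of_edge_orbit",
    "orbit_ids_for_size",
    "edge_orbit_ids_for_size",
    "orbit_column_count",
    "edge_orbit_column_count",
    "automorphisms",
    "export_atlas",
]


def _k4() -> list[tuple[int, int]]:
    return [(a, b) for a, b in combinations(range(4), 2)]


def _k5_minus(missing: list[tuple[int, int]]) -> list[tuple[int, int]]:
    gone = {tuple(sorted(e)) for e in missing}
    return [e for e in combinations(range(5), 2) if e not in gone]


#: Fixture table: adjacency of each graphlet in the published numbering.
#: Vertex labels within a graphlet are arbitrary; orbits are recomputed.
_GRAPHLET_EDGES: dict[int, list[tuple[int, int]]] = {
    0: [(0, 1)],                                          # single edge
    1: [(0, 1), (1, 2)],                                  # path P3
    2: [(0, 1), (0, 2), (1, 2)],                          # triangle
    3: [(0, 1), (1, 2), (2, 3)],                          # path P4
    4: [(0, 1), (0, 2), (0, 3)],                          # claw K1,3
    5: [(0, 1), (1, 2), (2, 3), (0, 3)],                  # cycle C4
    6: [(0, 1), (0, 2), (1, 2), (2, 3)],                  # paw
    7: [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)],          # diamond
    8: _k4(),                                             # K4
    9: [(0, 1), (1, 2), (2, 3), (3, 4)],                  # path P5
    10: [(0, 1), (1, 2), (2, 3), (2, 4)],                 # fork (subdivided claw)
    11: [(0, 1), (0, 2), (0, 3), (0, 4)],                 # star K1,4
    12: [(0, 2), (1, 2), (2, 3), (2, 4), (3, 4)],         # cricket
    13: [(0, 1), (1, 2), (2, 3), (0, 3), (0, 4)],         # C4 with a pendant
    14: [(0, 1), (0, 2), (1, 2), (0, 3), (1, 4)],         # bull
    15: [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)],         # cycle C5
    16: [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)],         # triangle with a 2-path
    17: [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (0, 4)],  # diamond, pendant at deg-3
    18: [(0, 1), (0, 4), (1, 4), (2, 3), (2, 4), (3, 4)],  # bowtie
    19: [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 4)],  # diamond, pendant at deg-2
    20: [(0, 3), (0, 4), (1, 3), (1, 4), (2, 3), (2, 4)],  # K2,3
    21: [(0, 1), (1, 2), (2, 3), (0, 3), (0, 4), (1, 4)],  # house
    22: [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4)],  # 3-page book
    23: [(0, 2), (0, 3), (0, 4), (1, 3), (1, 4), (2, 3), (2, 4)],  # K2,3 + edge
    24: [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (1, 4), (3, 4)],  # diamond + apex
    25: _k4() + [(0, 4)],                                 # K4 with a pendant
    26: _k5_minus([(0, 1), (0, 2)]),                      # K5 less two adjacent edges
    27: _k5_minus([(0, 1), (2, 3)]),                      # K5 less two disjoint edges
    28: _k5_minus([(0, 1)]),                              # K5 less one edge
    29: _k5_minus([]),                                    # K5
}

GRAPHLET_COUNT = 30


@dataclass(frozen=True)
class Graphlet:
    """A canonical small connected graph from the atlas."""

    id: int
    k: int
    edges: tuple[tuple[int, int], ...]
    degree_sequence: tuple[int, ...]


@dataclass(frozen=True)
class Orbit:
    """An automorphism equivalence class of a graphlet's vertices."""

    id: int
    graphlet_id: int
    members: frozenset[int]


@dataclass(frozen=True)
class EdgeOrbit:
    """An automorphism equivalence class of a graphlet's edges."""

    id: int
    graphlet_id: int
    members: frozenset[tuple[int, int]]


def _adjacency(k: int, edges: Iterable[tuple[int, int]]) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(k)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _automorphisms(k: int, edge_set: frozenset[tuple[int, int]]) -> list[tuple[int, ...]]:
    """All vertex permutations preserving the edge set (exhaustive; k <= 5)."""
    auts = []
    for perm in permutations(range(k)):
        mapped = {tuple(sorted((perm[u], perm[v]))) for u, v in edge_set}
        if mapped == edge_set:
            auts.append(perm)
    return auts


def _triangles_at(adj: Sequence[set[int]], v: int) -> int:
    nbrs = sorted(adj[v])
    return sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])


def _vertex_refinement_key(adj: Sequence[set[int]], v: int):
    """Isomorphism-invariant vertex key: degree, local triangle count, and the
    sorted (degree, triangle) pairs of the neighbours.

    One refinement round over (degree, triangles) separates the orbits of
    every graphlet in the atlas (asserted at import); it is also the key used
    to place a vertex of an identified induced subgraph into its orbit.
    """
    own = (len(adj[v]), _triangles_at(adj, v))
    nbr = tuple(sorted((len(adj[u]), _triangles_at(adj, u)) for u in adj[v]))
    return own + (nbr,)


def _edge_key(adj: Sequence[set[int]], u: int, v: int):
    return tuple(sorted((_vertex_refinement_key(adj, u), _vertex_refinement_key(adj, v))))


class _GraphletRecord:
    """Internal per-graphlet derived data (orbit partitions, lookup keys)."""

    __slots__ = (
        "id", "k", "edges", "edge_set", "adj", "masks", "degree_sequence",
        "n_triangles", "automorphisms", "node_orbit_classes", "node_orbit_ids",
        "vertex_orbit", "orbit_of_vkey", "edge_orbit_classes", "edge_orbit_ids",
        "edge_orbit_of", "edge_orbit_of_ekey", "vkeys",
    )

    def __init__(self, gid: int, edges: list[tuple[int, int]]):
        self.id = gid
        k = max(max(e) for e in edges) + 1
        self.k = k
        self.edges = tuple(tuple(sorted(e)) for e in edges)
        self.edge_set = frozenset(self.edges)
        self.adj = _adjacency(k, self.edges)
        self.masks = tuple(
            sum(1 << u for u in self.adj[v]) for v in range(k)
        )
        self.degree_sequence = tuple(sorted(len(s) for s in self.adj))
        self.n_triangles = sum(_triangles_at(self.adj, v) for v in range(k)) // 3
        self.automorphisms = _automorphisms(k, self.edge_set)

        # Node orbits: equivalence classes under the automorphism group,
        # ordered ascending by the refinement key (degree first).
        classes: dict[int, set[int]] = {}
        for v in range(k):
            rep = min(perm[v] for perm in self.automorphisms)
            classes.setdefault(rep, set()).add(v)
        self.vkeys = tuple(_vertex_refinement_key(self.adj, v) for v in range(k))
        ordered = sorted(classes.values(), key=lambda c: self.vkeys[min(c)])
        keys = [self.vkeys[min(c)] for c in ordered]
        if len(set(keys)) != len(keys):  # pragma: no cover - static fixture check
            raise AssertionError(f"orbit key collision in graphlet {gid}")
        for cls in ordered:
            if len({self.vkeys[v] for v in cls}) != 1:  # pragma: no cover
                raise AssertionError(f"orbit members disagree on key in G{gid}")
        self.node_orbit_classes = [frozenset(c) for c in ordered]
        self.node_orbit_ids: list[int] = []       # filled by _build_atlas
        self.vertex_orbit = {}                    # vertex -> global orbit id
        self.orbit_of_vkey = {}                   # vkey -> global orbit id

        # Edge orbits, ordered by the sorted pair of endpoint orbit positions.
        eclasses: dict[tuple[int, int], set[tuple[int, int]]] = {}
        for e in self.edges:
            rep = min(tuple(sorted((perm[e[0]], perm[e[1]]))) for perm in self.automorphisms)
            eclasses.setdefault(rep, set()).add(e)
        local_orbit = {v: i for i, c in enumerate(self.node_orbit_classes) for v in c}

        def eorder(cls: set[tuple[int, int]]):
            u, v = min(cls)
            pair = tuple(sorted((local_orbit[u], local_orbit[v])))
            return (pair, _edge_key(self.adj, u, v), min(cls))

        eordered = sorted(eclasses.values(), key=eorder)
        ekeys = [_edge_key(self.adj, *min(c)) for c in eordered]
        if len(set(ekeys)) != len(ekeys):  # pragma: no cover - static fixture check
            raise AssertionError(f"edge-orbit key collision in graphlet {gid}")
        self.edge_orbit_classes = [frozenset(c) for c in eordered]
        self.edge_orbit_ids: list[int] = []
        self.edge_orbit_of = {}                   # edge -> global edge-orbit id
        self.edge_orbit_of_ekey = {}              # ekey -> global edge-orbit id


_RECORDS: list[_GraphletRecord] = []
_BY_K: dict[int, list[_GraphletRecord]] = {}
_GRAPHLET_KEY: dict[tuple, int] = {}
_ORBIT_TO_GRAPHLET: list[int] = []
_EDGE_ORBIT_TO_GRAPHLET: list[int] = []


def _build_atlas() -> None:
    next_orbit = 0
    next_edge_orbit = 0
    for gid in range(GRAPHLET_COUNT):
        rec = _GraphletRecord(gid, _GRAPHLET_EDGES[gid])
        _RECORDS.append(rec)
        _BY_K.setdefault(rec.k, []).append(rec)

        gkey = (rec.k, rec.degree_sequence, rec.n_triangles)
        if gkey in _GRAPHLET_KEY:  # pragma: no cover - static fixture check
            raise AssertionError(f"graphlet key collision: G{gid} vs G{_GRAPHLET_KEY[gkey]}")
        _GRAPHLET_KEY[gkey] = gid

        for cls in rec.node_orbit_classes:
            rec.node_orbit_ids.append(next_orbit)
            for v in cls:
                rec.vertex_orbit[v] = next_orbit
            rec.orbit_of_vkey[rec.vkeys[min(cls)]] = next_orbit
            _ORBIT_TO_GRAPHLET.append(gid)
            next_orbit += 1
        for cls in rec.edge_orbit_classes:
            rec.edge_orbit_ids.append(next_edge_orbit)
            for e in cls:
                rec.edge_orbit_of[e] = next_edge_orbit
            rec.edge_orbit_of_ekey[_edge_key(rec.adj, *min(cls))] = next_edge_orbit
            _EDGE_ORBIT_TO_GRAPHLET.append(gid)
            next_edge_orbit += 1

    if next_orbit != 73:  # pragma: no cover - static fixture check
        raise AssertionError(f"expected 73 node orbits, built {next_orbit}")


_build_atlas()

NODE_ORBIT_COUNT = len(_ORBIT_TO_GRAPHLET)
EDGE_ORBIT_COUNT = len(_EDGE_ORBIT_TO_GRAPHLET)


def _record(graphlet: Graphlet | int) -> _GraphletRecord:
    gid = graphlet.id if isinstance(graphlet, Graphlet) else graphlet
    if not 0 <= gid < GRAPHLET_COUNT:
        raise IdentificationError(f"unknown graphlet id {gid}")
    return _RECORDS[gid]


def enumerate_graphlets(k: int) -> list[Graphlet]:
    """All connected non-isomorphic graphs on ``k`` nodes, in atlas order."""
    if k not in _BY_K:
        raise UnsupportedSizeError(f"graphlet size must be 2..5, got {k}")
    return [
        Graphlet(rec.id, rec.k, rec.edges, rec.degree_sequence) for rec in _BY_K[k]
    ]


def node_orbits(graphlet: Graphlet | int) -> list[Orbit]:
    """The automorphism node orbits of a graphlet, in atlas order."""
    rec = _record(graphlet)
    return [
        Orbit(oid, rec.id, cls)
        for oid, cls in zip(rec.node_orbit_ids, rec.node_orbit_classes)
    ]


def edge_orbits(graphlet: Graphlet | int) -> list[EdgeOrbit]:
    """The automorphism edge orbits of a graphlet, in atlas order."""
    rec = _record(graphlet)
    return [
        EdgeOrbit(eoid, rec.id, cls)
        for eoid, cls in zip(rec.edge_orbit_ids, rec.edge_orbit_classes)
    ]


def automorphisms(graphlet: Graphlet | int) -> list[tuple[int, ...]]:
    """The automorphism group of a graphlet as vertex permutations."""
    return list(_record(graphlet).automorphisms)


def graphlet_of_orbit(i: int) -> int:
    """m(i): the id of the graphlet containing node orbit ``i``."""
    if not 0 <= i < NODE_ORBIT_COUNT:
        raise IdentificationError(f"unknown orbit id {i}")
    return _ORBIT_TO_GRAPHLET[i]


def graphlet_of_edge_orbit(i: int) -> int:
    """The id of the graphlet containing edge orbit ``i``."""
    if not 0 <= i < EDGE_ORBIT_COUNT:
        raise IdentificationError(f"unknown edge orbit id {i}")
    return _EDGE_ORBIT_TO_GRAPHLET[i]


def orbit_ids_for_size(k: int) -> list[int]:
    """Global node-orbit ids carried by graphlets on exactly ``k`` nodes."""
    if k not in _BY_K:
        raise UnsupportedSizeError(f"graphlet size must be 2..5, got {k}")
    return [oid for rec in _BY_K[k] for oid in rec.node_orbit_ids]


def edge_orbit_ids_for_size(k: int) -> list[int]:
    if k not in _BY_K:
        raise UnsupportedSizeError(f"graphlet size must be 2..5, got {k}")
    return [eoid for rec in _BY_K[k] for eoid in rec.edge_orbit_ids]


def orbit_column_count(k: int) -> int:
    """Number of node-orbit columns for counting up to size ``k`` (sizes 2..k)."""
    return orbit_ids_for_size(k)[-1] + 1


def edge_orbit_column_count(k: int) -> int:
    return edge_orbit_ids_for_size(k)[-1] + 1


def _normalize_input(edges: Iterable) -> tuple[int, list[set[int]], dict]:
    """Relabel an edge list over arbitrary hashables to 0..k-1."""
    edge_list = [tuple(e) for e in edges]
    labels = sorted({x for e in edge_list for x in e}, key=repr)
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    if not 2 <= k <= 5:
        raise IdentificationError(f"identification supports 2..5 nodes, got {k}")
    adj: list[set[int]] = [set() for _ in range(k)]
    for u, v in edge_list:
        if u == v:
            raise IdentificationError("self-loop in identification input")
        adj[index[u]].add(index[v])
        adj[index[v]].add(index[u])
    # connectivity
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    if len(seen) != k:
        raise IdentificationError("identification input is disconnected")
    return k, adj, index


def _classify(k: int, adj: Sequence[set[int]]) -> _GraphletRecord:
    degs = tuple(sorted(len(s) for s in adj))
    ntri = sum(_triangles_at(adj, v) for v in range(k)) // 3
    gid = _GRAPHLET_KEY.get((k, degs, ntri))
    if gid is None:  # pragma: no cover - every connected 2..5 graph is in the table
        raise IdentificationError("input does not match any atlas graphlet")
    return _RECORDS[gid]


def identify(edges: Iterable, marked=None) -> tuple[int, int | None]:
    """Identify a small connected graph and the orbit of a marked vertex.

    ``edges`` is an iterable of 2-tuples over arbitrary vertex labels;
    ``marked`` (optional) is one of those labels.  Returns
    ``(graphlet_id, orbit_id)`` with ``orbit_id`` ``None`` when no vertex is
    marked.  The result is invariant under relabeling of the input.
    """
    k, adj, index = _normalize_input(edges)
    rec = _classify(k, adj)
    if marked is None:
        return rec.id, None
    if marked not in index:
        raise IdentificationError(f"marked vertex {marked!r} not in the input graph")
    vkey = _vertex_refinement_key(adj, index[marked])
    return rec.id, rec.orbit_of_vkey[vkey]


def identify_edge(edges: Iterable, marked_edge) -> tuple[int, int]:
    """Identify a small connected graph and the edge orbit of a marked edge."""
    k, adj, index = _normalize_input(edges)
    rec = _classify(k, adj)
    u, v = marked_edge
    if u not in index or v not in index:
        raise IdentificationError("marked edge endpoints not in the input graph")
    iu, iv = index[u], index[v]
    if iv not in adj[iu]:
        raise IdentificationError("marked pair is not an edge of the input graph")
    return rec.id, rec.edge_orbit_of_ekey[_edge_key(adj, iu, iv)]


def export_atlas(stream: TextIO) -> None:
    """Write the atlas (graphlets, node orbits, edge orbits) as plain text."""
    for rec in _RECORDS:
        edges = ",".join(f"{u}-{v}" for u, v in rec.edges)
        stream.write(f"graphlet {rec.id} k={rec.k} edges={edges}\n")
    for rec in _RECORDS:
        for oid, cls in zip(rec.node_orbit_ids, rec.node_orbit_classes):
            members = ",".join(str(v) for v in sorted(cls))
            stream.write(f"orbit {oid} graphlet={rec.id} members={members}\n")
    for rec in _RECORDS:
        for eoid, cls in zip(rec.edge_orbit_ids, rec.edge_orbit_classes):
            members = ",".join(f"{u}-{v}" for u, v in sorted(cls))
            stream.write(f"edge-orbit {eoid} graphlet={rec.id} members={members}\n")
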