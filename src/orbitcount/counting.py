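"""The four-step orbit-counting engine.

Given a host graph H and k in {4, 5}, per-vertex (or per-edge) orbit
counts are obtained by

1. precomputing common-neighbour counts c(S) for all vertex sets the
   equation right-hand sides can ask for (singletons are degrees; pairs;
   for k = 5 additionally connected triples),
2. enumerating k-cliques directly (the one orbit the triangular system
   cannot produce),
3. enumerating the connected (k-1)-vertex induced subgraphs of H once and
   accumulating every equation's right-hand side at each touched vertex
   (or edge), and
4. back-substituting through the triangular system in exact integer
   arithmetic, per vertex (or edge).

Counts for sizes 2 and 3 fall below the system construction and use
closed forms.  The 4-cycle orbit needs common-neighbour counts of vertex
pairs at distance two; these are recomputed per focal vertex into O(n)
scratch instead of being tabulated, keeping the k = 4 space bound at
O(n d).  All counts are exact arbitrary-precision integers; a triangular
solve that fails to divide exactly or goes negative raises
:class:`IntegrityError` rather than returning a wrong matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

from . import atlas
from .atlas import _GRAPHLET_KEY, _RECORDS
from .equations import (
    OrbitEquation,
    build_edge_system,
    build_node_system,
    find_embedding,
)
from .errors import IntegrityError, UnsupportedSizeError
from .graph import HostGraph

__all__ = [
    "CommonNeighborTable",
    "OrbitCountMatrix",
    "precompute_common_neighbors",
    "count_cliques",
    "accumulate_rhs",
    "solve_counts",
    "count_node_orbits",
    "count_edge_orbits",
]


@dataclass(frozen=True)
class OrbitCountMatrix:
    """Exact integer orbit counts: one row per vertex (node mode) or per
    input edge (edge mode); columns ordered by atlas orbit id."""

    mode: str
    k: int
    rows: tuple[tuple[int, ...], ...]


class CommonNeighborTable:
    """c(S) = number of common neighbours of the vertex set S in the host.

    Stores pairs (for k = 4 only adjacent pairs, matching the O(n d) space
    bound; for k = 5 every pair with a common neighbour) and, for k = 5,
    connected triples.  Absent keys mean c(S) = 0; singletons are degrees.
    """

    __slots__ = ("k", "degrees", "pairs", "triples")

    def __init__(self, k: int, degrees: Sequence[int], pairs: dict, triples: dict):
        self.k = k
        self.degrees = degrees
        self.pairs = pairs
        self.triples = triples

    def c(self, vertices: tuple[int, ...]) -> int:
        """c(S) for a sorted vertex tuple of size 1..3."""
        if len(vertices) == 1:
            return self.degrees[vertices[0]]
        if len(vertices) == 2:
            return self.pairs.get(vertices, 0)
        return self.triples.get(vertices, 0)


def precompute_common_neighbors(h: HostGraph, k: int) -> CommonNeighborTable:
    """Iterate each vertex w and the small subsets of N(w), incrementing
    c(S) for every subset S; connected-set filtering applies at |S| = k-2."""
    if k not in (4, 5):
        raise UnsupportedSizeError(f"common-neighbour tables support k in {{4, 5}}, got {k}")
    masks = h.masks
    pairs: dict[tuple[int, int], int] = {}
    triples: dict[tuple[int, int, int], int] = {}
    for w in range(h.n):
        nb = h.adj[w]
        for i, u in enumerate(nb):
            mu = masks[u]
            for v in nb[i + 1:]:
                if k == 4 and not mu >> v & 1:
                    continue  # k = 4 stores connected 2-sets only
                key = (u, v)
                pairs[key] = pairs.get(key, 0) + 1
        if k == 5:
            for a, b, c in combinations(nb, 3):
                ne = (masks[a] >> b & 1) + (masks[a] >> c & 1) + (masks[b] >> c & 1)
                if ne >= 2:  # the triple induces a connected subgraph
                    key = (a, b, c)
                    triples[key] = triples.get(key, 0) + 1
    return CommonNeighborTable(k, h.degrees, pairs, triples)


def _iter_bits(x: int) -> Iterator[int]:
    while x:
        b = x & -x
        yield b.bit_length() - 1
        x ^= b


def count_cliques(h: HostGraph, k: int, per_edge: bool = False) -> list[int]:
    """Exact K_k membership counts per vertex (or per input edge).

    Cliques are enumerated once each by growing inside successive common
    neighbourhoods restricted to higher vertex ids.
    """
    if k not in (4, 5):
        raise UnsupportedSizeError(f"clique counting supports k in {{4, 5}}, got {k}")
    masks = h.masks
    out = [0] * (h.e if per_edge else h.n)
    eidx = h.edge_index

    def record(members: tuple[int, ...]) -> None:
        if per_edge:
            for p, q in combinations(members, 2):
                out[eidx[(p, q) if p < q else (q, p)]] += 1
        else:
            for v in members:
                out[v] += 1

    for u, v in eidx:  # normalized u < v
        com = masks[u] & masks[v] >> (v + 1) << (v + 1)
        for a in _iter_bits(com):
            coma = com & masks[a] >> (a + 1) << (a + 1)
            if k == 4:
                for b in _iter_bits(coma):
                    record((u, v, a, b))
            else:
                for b in _iter_bits(coma):
                    comb = coma & masks[b] >> (b + 1) << (b + 1)
                    for c in _iter_bits(comb):
                        record((u, v, a, b, c))
    return out


def _connected_msets(h: HostGraph, m: int, root: int | None = None) -> Iterator[tuple[int, ...]]:
    """Enumerate every connected m-vertex subset exactly once (Wernicke-style
    growth by exclusive neighbours).  With ``root`` given, enumerate exactly
    the connected m-sets containing ``root`` instead."""
    masks = h.masks
    full = (1 << h.n) - 1

    def extend(sub: tuple[int, ...], ext: int, nbhd: int, allowed: int) -> Iterator[tuple[int, ...]]:
        if len(sub) == m:
            yield sub
            return
        while ext:
            b = ext & -ext
            w = b.bit_length() - 1
            ext ^= b
            grow = masks[w] & ~nbhd & allowed
            yield from extend(sub + (w,), ext | grow, nbhd | grow | b, allowed)

    roots = range(h.n) if root is None else (root,)
    for r in roots:
        allowed = full & ~((1 << (r + 1)) - 1) if root is None else full & ~(1 << r)
        ext0 = masks[r] & allowed
        yield from extend((r,), ext0, ext0 | (1 << r), allowed)


def _subgraph_profile(h: HostGraph, W: tuple[int, ...]):
    """Classify an induced connected subgraph: atlas record, per-member
    refinement keys, and the member adjacency (as index lists)."""
    masks = h.masks
    m = len(W)
    sub = 0
    for w in W:
        sub |= 1 << w
    im = [masks[w] & sub for w in W]
    pos = {w: i for i, w in enumerate(W)}
    nbrs = [[pos[b] for b in _iter_bits(mask)] for mask in im]
    deg = [len(ns) for ns in nbrs]
    tri = [0] * m
    ntri = 0
    for i in range(m):
        for j in nbrs[i]:
            if j > i:
                t = (im[i] & im[j]).bit_count()
                tri[i] += t
                tri[j] += t
                ntri += t
    ntri //= 3
    tri = [t // 2 for t in tri]  # each triangle is seen from two incident edges
    rec = _RECORDS[_GRAPHLET_KEY[(m, tuple(sorted(deg)), ntri)]]
    dt = [(deg[i], tri[i]) for i in range(m)]
    vkeys = [
        (deg[i], tri[i], tuple(sorted(dt[j] for j in nbrs[i]))) for i in range(m)
    ]
    return rec, vkeys, nbrs


def _host_adjacency_test(masks):
    return lambda a, b: bool(masks[a] >> b & 1)


def _rhs_groups(system: Sequence[OrbitEquation]):
    groups: dict[tuple[int, int], list] = {}
    for ei, eq in enumerate(system):
        if eq.special_c4:
            continue
        spec = eq.rhs
        ext = tuple(
            (tuple(sorted(E)), corr)
            for E, corr in zip(spec.extension_sets, spec.corrections)
        )
        groups.setdefault(
            (spec.reduced_graphlet_id, spec.marked_orbit), []
        ).append((ei, spec, ext))
    return groups


def _two_hop_scratch(h: HostGraph, x: int) -> dict[int, int]:
    """c(x, w) for every vertex w at distance two from x (O(n) scratch)."""
    masks = h.masks
    mx = masks[x]
    cnt: dict[int, int] = {}
    for x1 in h.adj[x]:
        for w in _iter_bits(masks[x1] & ~mx & ~(1 << x)):
            cnt[w] = cnt.get(w, 0) + 1
    return cnt


def _special_c4_index(system: Sequence[OrbitEquation]) -> int | None:
    for ei, eq in enumerate(system):
        if eq.special_c4:
            return ei
    return None


def _accumulate_occurrence(
    h, rec, vkeys, W, groups, cn, sink, marked_kind
) -> None:
    """Distribute one induced (k-1)-subgraph occurrence into the per-vertex
    (marked_kind='node') or per-edge ('edge') right-hand sides."""
    adjacency = _host_adjacency_test(h.masks)
    if marked_kind == "node":
        targets = [(rec.orbit_of_vkey[vkeys[i]], x, {"v": x, "i": i}) for i, x in enumerate(W)]
    else:
        targets = []
        for i in range(len(W)):
            for j in range(i + 1, len(W)):
                if h.masks[W[i]] >> W[j] & 1:
                    ek = tuple(sorted((vkeys[i], vkeys[j])))
                    u, v = W[i], W[j]
                    row = h.edge_index[(u, v) if u < v else (v, u)]
                    targets.append((rec.edge_orbit_of_ekey[ek], row, {"uv": (u, v)}))
    for marked_id, sink_row, info in targets:
        glist = groups.get((rec.id, marked_id))
        if not glist:
            continue
        phi = None
        for ei, spec, ext in glist:
            if phi is None:
                if marked_kind == "node":
                    pins = ({spec.marked_vertex: info["v"]},)
                else:
                    u, v = info["uv"]
                    a0, b0 = spec.marked_edge
                    pins = ({a0: u, b0: v}, {a0: v, b0: u})
                for pin in pins:
                    phi = find_embedding(rec.id, W, adjacency, pin)
                    if phi is not None:
                        break
                if phi is None:  # pragma: no cover - identification guarantees one
                    raise IntegrityError("no embedding for an identified occurrence")
            total = 0
            for E, corr in ext:
                img = tuple(sorted(phi[v] for v in E))
                total += cn.c(img) - corr
            sink[sink_row][ei] += total


def accumulate_rhs(
    h: HostGraph, x: int, system: Sequence[OrbitEquation], cn: CommonNeighborTable
) -> list[int]:
    """Right-hand-side vector of the node system at one focal vertex: the sum
    of the extension terms over every induced occurrence of each equation's
    reduced graphlet at ``x``, including the special 4-cycle equation."""
    k = cn.k
    groups = _rhs_groups(system)
    sink = _SingleRowSink(x, [0] * len(system))
    for W in _connected_msets(h, k - 1, root=x):
        rec, vkeys, _ = _subgraph_profile(h, W)
        _accumulate_occurrence(h, rec, vkeys, W, groups, cn, sink, "node")
    vec = sink.row
    si = _special_c4_index(system)
    if si is not None:
        cnt = _two_hop_scratch(h, x)
        vec[si] += sum(c * (c - 1) for c in cnt.values())
    return vec


class _NullRow:
    __slots__ = ()

    def __setitem__(self, key, value):
        pass

    def __getitem__(self, key):
        return 0


class _SingleRowSink:
    """Row container that keeps one focal row and discards all others; lets
    the shared occurrence-accumulation loop serve the per-vertex API."""

    __slots__ = ("keep", "row", "void")

    def __init__(self, keep: int, row: list[int]):
        self.keep = keep
        self.row = row
        self.void = _NullRow()

    def __getitem__(self, key):
        return self.row if key == self.keep else self.void


def _edges_of_target(eq: OrbitEquation) -> int:
    if eq.edge_mode:
        gid = atlas.graphlet_of_edge_orbit(eq.target_orbit)
    else:
        gid = atlas.graphlet_of_orbit(eq.target_orbit)
    return len(_RECORDS[gid].edges)


def solve_counts(
    system: Sequence[OrbitEquation], rhs: Sequence[int], clique_count: int
) -> dict[int, int]:
    """Back-substitute the triangular system for one vertex or edge.

    ``rhs`` is indexed like ``system``; the directly-enumerated clique-orbit
    count seeds the recursion.  Exact divisibility and nonnegativity of
    every solved count are enforced as correctness witnesses.
    """
    if not system:
        raise IntegrityError("empty equation system")
    edge_mode = system[0].edge_mode
    k = (
        _RECORDS[atlas.graphlet_of_edge_orbit(system[0].target_orbit)].k
        if edge_mode
        else _RECORDS[atlas.graphlet_of_orbit(system[0].target_orbit)].k
    )
    clique_orbit = (
        atlas.edge_orbit_ids_for_size(k)[-1]
        if edge_mode
        else atlas.orbit_ids_for_size(k)[-1]
    )
    if clique_count < 0:
        raise IntegrityError("negative clique count")
    counts: dict[int, int] = {clique_orbit: clique_count}
    order = sorted(
        range(len(system)),
        key=lambda ei: (-_edges_of_target(system[ei]), -system[ei].target_orbit),
    )
    for ei in order:
        eq = system[ei]
        t = eq.target_orbit
        acc = rhs[ei]
        for p, f in eq.lhs.items():
            if p != t:
                acc -= f * counts[p]
        ft = eq.lhs[t]
        q, r = divmod(acc, ft)
        if r != 0 or q < 0:
            raise IntegrityError(
                f"triangular solve failed at orbit {t}: {acc} / {ft} "
                f"(remainder {r}); input is corrupted or counts overflowed"
            )
        counts[t] = q
    return counts


def _closed_form_node(h: HostGraph) -> list[list[int]]:
    """Orbits 0-3 (edge, path end/centre, triangle) from degrees and triangles."""
    masks = h.masks
    tri = [0] * h.n
    for u, v in h.edge_index:
        t = (masks[u] & masks[v]).bit_count()
        # each common neighbour w closes one triangle at u and at v; the
        # triangle at w is found from its own incident edges
        tri[u] += t
        tri[v] += t
    tri = [t // 2 for t in tri]
    rows = []
    for v in range(h.n):
        d = h.degrees[v]
        o3 = tri[v]
        o2 = d * (d - 1) // 2 - o3
        o1 = sum(h.degrees[u] - 1 for u in h.adj[v]) - 2 * o3
        rows.append([d, o1, o2, o3])
    return rows


def _closed_form_edge(h: HostGraph) -> list[list[int]]:
    """Edge orbits 0-2 (the edge; path; triangle) per input edge."""
    masks = h.masks
    rows = []
    for u, v in h.edges:
        t = (masks[u] & masks[v]).bit_count()
        o1 = (h.degrees[u] - 1 - t) + (h.degrees[v] - 1 - t)
        rows.append([1, o1, t])
    return rows


def _batch_rhs(h: HostGraph, k: int, system, cn, mode: str):
    nrows = h.n if mode == "node" else h.e
    sink = [[0] * len(system) for _ in range(nrows)]
    groups = _rhs_groups(system)
    for W in _connected_msets(h, k - 1):
        rec, vkeys, _ = _subgraph_profile(h, W)
        _accumulate_occurrence(h, rec, vkeys, W, groups, cn, sink, mode)
    si = _special_c4_index(system)
    if si is not None:
        if mode == "node":
            for x in range(h.n):
                cnt = _two_hop_scratch(h, x)
                sink[x][si] += sum(c * (c - 1) for c in cnt.values())
        else:
            masks = h.masks
            for s in range(h.n):
                cnt = _two_hop_scratch(h, s)
                for t in h.adj[s]:
                    row = h.edge_index[(s, t) if s < t else (t, s)]
                    acc = 0
                    for w in _iter_bits(masks[t] & ~masks[s] & ~(1 << s)):
                        acc += cnt.get(w, 0) - 1
                    sink[row][si] += acc
    return sink


def _count(h: HostGraph, k: int, mode: str) -> OrbitCountMatrix:
    if k not in (4, 5):
        raise UnsupportedSizeError(f"orbit counting supports k in {{4, 5}}, got {k}")
    if mode == "node":
        cols = atlas.orbit_column_count(k)
        rows = [[0] * cols for _ in range(h.n)]
        for v, base in enumerate(_closed_form_node(h)):
            rows[v][0:4] = base
    else:
        cols = atlas.edge_orbit_column_count(k)
        rows = [[0] * cols for _ in range(h.e)]
        for r, base in enumerate(_closed_form_edge(h)):
            rows[r][0:3] = base
    for kk in range(4, k + 1):
        system = build_node_system(kk) if mode == "node" else build_edge_system(kk)
        cn = precompute_common_neighbors(h, kk)
        cliques = count_cliques(h, kk, per_edge=(mode == "edge"))
        rhs = _batch_rhs(h, kk, system, cn, mode)
        for r in range(len(rows)):
            for oid, val in solve_counts(system, rhs[r], cliques[r]).items():
                rows[r][oid] = val
    return OrbitCountMatrix(mode, k, tuple(tuple(r) for r in rows))


def count_node_orbits(h: HostGraph, k: int) -> OrbitCountMatrix:
    """Per-vertex counts for every node orbit of sizes 2..k."""
    return _count(h, k, "node")


def count_edge_orbits(h: HostGraph, k: int) -> OrbitCountMatrix:
    """Per-edge counts for every edge orbit of sizes 2..k, rows in input
    edge order."""
    return _count(h, k, "edge")
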