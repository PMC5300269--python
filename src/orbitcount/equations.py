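"""Automatic derivation of the triangular orbit-count equation systems.

For every node orbit (and edge orbit) of the 4- and 5-node graphlets except
the clique orbit, one linear relation is derived that ties the orbit's
count at a host vertex ``x`` (or host edge) to counts of orbits in denser
graphlets.  The derivation removes a carefully chosen node ``y`` from the
graphlet ``G_a`` containing the target orbit, leaving a connected reduced
graphlet ``G' = G_a \\ {y}``; re-attaching a new vertex to each *extension
set* ``E`` of ``G'`` vertices reconstructs ``G_a`` with ``x`` back in the
target orbit.  Summed over the induced occurrences of ``G'`` in a host
graph, the number of candidate re-attachment vertices is

    sum_E ( c(E in H) - c(E in G') )

which over-counts: the candidate may also connect to the remaining
``G'`` vertices, producing denser graphlets.  The over-count of each such
orbit ``p`` is a host-independent positive integer coefficient ``f_p``
obtained by counting the ways the denser graphlet can be built from ``G'``
by one attachment with ``x`` held fixed.  The resulting system is
triangular in the number of graphlet edges and solvable in exact integer
arithmetic once the clique orbit is counted directly.

The removable node ``y`` must satisfy three conditions so that every
``c(E)`` the right-hand sides need is cheap to precompute: (i) its degree
is at most ``k - 2``; (ii) its removal keeps the graphlet connected;
(iii) if its degree equals ``k - 2``, its neighbours induce a connected
graph.  A valid ``y`` exists for every graphlet except complete graphs
(counted directly) and the 4-cycle, whose single orbit gets a special
equation with ``y`` taken adjacent to ``x``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Iterable, Mapping

from . import atlas
from .atlas import _record
from .errors import OrbitCountError, UnsupportedSizeError

__all__ = [
    "CompleteGraphletSignal",
    "CycleSpecialSignal",
    "LayerDecomposition",
    "ExtensionSpec",
    "OrbitEquation",
    "layer_decomposition",
    "select_y",
    "extension_sets",
    "extension_sets_edge",
    "lhs_coefficients",
    "lhs_coefficients_edge",
    "build_node_system",
    "build_edge_system",
    "system_to_json",
]


class CompleteGraphletSignal(OrbitCountError):
    """No valid removable node exists in a complete graphlet: every vertex has
    degree k-1.  The clique orbit is counted by direct enumeration instead."""


class CycleSpecialSignal(OrbitCountError):
    """The 4-cycle admits no removable node satisfying all three conditions;
    its orbit gets the special equation with y adjacent to x."""


@dataclass(frozen=True)
class LayerDecomposition:
    """Vertices of a graphlet grouped by distance from a source vertex."""

    source: int
    layers: tuple[frozenset[int], ...]

    @property
    def u(self) -> int:
        """Eccentricity of the source: index of the last non-empty layer."""
        return len(self.layers) - 1


@dataclass(frozen=True)
class ExtensionSpec:
    """Right-hand-side recipe of one equation.

    ``extension_sets`` are subsets of the reduced graphlet's (atlas-label)
    vertices such that attaching a new vertex adjacent to exactly that set
    rebuilds the target graphlet with the marked vertex (or edge) in the
    target orbit.  ``corrections`` are the common-neighbour counts of each
    set inside the reduced graphlet itself.  ``marked_vertex`` is the atlas
    vertex of the reduced graphlet the sets are expressed against; in edge
    mode ``marked_edge`` plays that role and ``marked_orbit`` is an edge
    orbit id.
    """

    reduced_graphlet_id: int
    marked_orbit: int
    extension_sets: tuple[frozenset[int], ...]
    corrections: tuple[int, ...]
    marked_vertex: int | None = None
    marked_edge: tuple[int, int] | None = None


@dataclass(frozen=True)
class OrbitEquation:
    """One derived relation: ``sum_p lhs[p] * o_p = rhs`` summed over
    occurrences of the reduced graphlet.  ``special_c4`` marks the 4-cycle
    equation whose right side needs common-neighbour counts of vertex pairs
    at distance two (recomputed per focal vertex in O(n) scratch space)."""

    target_orbit: int
    lhs: Mapping[int, int]
    rhs: ExtensionSpec
    edge_mode: bool = False
    special_c4: bool = False


def layer_decomposition(graphlet, x: int) -> LayerDecomposition:
    """BFS layers L_0 = {x}, L_1, ... up to the eccentricity of ``x``."""
    rec = _record(graphlet)
    dist = {x: 0}
    frontier = [x]
    layers = [frozenset([x])]
    while frontier:
        nxt = []
        for v in frontier:
            for w in rec.adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        if nxt:
            layers.append(frozenset(nxt))
        frontier = nxt
    if len(dist) != rec.k:
        raise OrbitCountError(f"graphlet G{rec.id} is not connected")  # pragma: no cover
    return LayerDecomposition(x, tuple(layers))


def _connected_after_removal(rec, removed: int) -> bool:
    remaining = [v for v in range(rec.k) if v != removed]
    if not remaining:
        return False
    seen = {remaining[0]}
    stack = [remaining[0]]
    while stack:
        for w in rec.adj[stack.pop()]:
            if w != removed and w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == rec.k - 1


def _neighbours_connected(rec, y: int) -> bool:
    nbrs = sorted(rec.adj[y])
    if len(nbrs) <= 1:
        return True
    seen = {nbrs[0]}
    stack = [nbrs[0]]
    nbr_set = set(nbrs)
    while stack:
        for w in rec.adj[stack.pop()]:
            if w in nbr_set and w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(nbrs)


def _valid_y(rec, y: int) -> bool:
    d = len(rec.adj[y])
    if d > rec.k - 2:
        return False
    if not _connected_after_removal(rec, y):
        return False
    if d == rec.k - 2 and not _neighbours_connected(rec, y):
        return False
    return True


def select_y(graphlet, x: int, forbidden: int | None = None) -> int:
    """Pick the removable node: the lowest-degree valid vertex of the farthest
    BFS layer from ``x``, falling back to the next layer in the one special
    case; ties break on the smallest vertex label.  ``forbidden`` excludes
    the second endpoint of a marked edge in edge-orbit mode.

    Raises :class:`CompleteGraphletSignal` for complete graphlets and
    :class:`CycleSpecialSignal` for the 4-cycle.
    """
    rec = _record(graphlet)
    if all(len(nbrs) == rec.k - 1 for nbrs in rec.adj):
        raise CompleteGraphletSignal(
            f"G{rec.id} is complete: count its orbit by direct enumeration"
        )
    layers = layer_decomposition(rec.id, x).layers
    for layer in (layers[-1], layers[-2]) if len(layers) > 2 else (layers[-1],):
        for y in sorted(layer, key=lambda v: (len(rec.adj[v]), v)):
            if y == x or y == forbidden:
                continue
            if _valid_y(rec, y):
                return y
    if rec.id == 5:
        raise CycleSpecialSignal("no removable node in C4 satisfies the conditions")
    raise OrbitCountError(  # pragma: no cover - excluded by the existence proof
        f"no valid removable node in G{rec.id} for x={x}, forbidden={forbidden}"
    )


def _common_in_graphlet(rec, E: Iterable[int]) -> int:
    inter = None
    for v in E:
        inter = rec.masks[v] if inter is None else inter & rec.masks[v]
    return int(inter).bit_count()


def _attach(rec, E: Iterable[int]) -> list[tuple[int, int]]:
    new = rec.k
    return list(rec.edges) + [(v, new) for v in sorted(E)]


def extension_sets(gprime, x: int, target_graphlet, target_orbit: int) -> ExtensionSpec:
    """All vertex sets of the reduced graphlet whose one-vertex attachment
    rebuilds the target graphlet with ``x`` in the target orbit, plus the
    common-neighbour corrections of each set inside the reduced graphlet."""
    rec = _record(gprime)
    target = _record(target_graphlet)
    marked = rec.vertex_orbit[x]
    sets, corrs = [], []
    for r in range(1, rec.k + 1):
        for E in combinations(range(rec.k), r):
            try:
                got = atlas.identify(_attach(rec, E), marked=x)
            except atlas.IdentificationError:  # pragma: no cover - always connected
                continue
            if got == (target.id, target_orbit):
                sets.append(frozenset(E))
                corrs.append(_common_in_graphlet(rec, E))
    if not sets:
        raise OrbitCountError(
            f"no extension of G{rec.id} reaches orbit {target_orbit}: invalid y"
        )
    return ExtensionSpec(
        reduced_graphlet_id=rec.id,
        marked_orbit=marked,
        extension_sets=tuple(sets),
        corrections=tuple(corrs),
        marked_vertex=x,
    )


def extension_sets_edge(
    gprime, marked_edge: tuple[int, int], target_graphlet, target_edge_orbit: int
) -> ExtensionSpec:
    """Edge-orbit variant of :func:`extension_sets`: the marked element is an
    edge of the reduced graphlet and the target is an edge orbit."""
    rec = _record(gprime)
    target = _record(target_graphlet)
    me = tuple(sorted(marked_edge))
    marked = rec.edge_orbit_of[me]
    sets, corrs = [], []
    for r in range(1, rec.k + 1):
        for E in combinations(range(rec.k), r):
            got = atlas.identify_edge(_attach(rec, E), me)
            if got == (target.id, target_edge_orbit):
                sets.append(frozenset(E))
                corrs.append(_common_in_graphlet(rec, E))
    if not sets:
        raise OrbitCountError(
            f"no extension of G{rec.id} reaches edge orbit {target_edge_orbit}: invalid y"
        )
    return ExtensionSpec(
        reduced_graphlet_id=rec.id,
        marked_orbit=marked,
        extension_sets=tuple(sets),
        corrections=tuple(corrs),
        marked_edge=me,
    )


def _induced_edges(rec, keep: tuple[int, ...]) -> list[tuple[int, int]]:
    kept = set(keep)
    return [e for e in rec.edges if e[0] in kept and e[1] in kept]


def find_embedding(
    gprime, vertices: tuple[int, ...], adjacency_test, pinned: Mapping[int, int],
) -> dict[int, int] | None:
    """Edge-preserving bijection from the reduced graphlet onto an isomorphic
    vertex set, honouring pre-pinned assignments.  ``adjacency_test(a, b)``
    answers adjacency on the target side.  Returns one embedding or None."""
    rec = _record(gprime)
    free_src = [v for v in range(rec.k) if v not in pinned]
    used = set(pinned.values())
    free_dst = [v for v in vertices if v not in used]
    for perm in permutations(free_dst):
        phi = dict(pinned)
        phi.update(zip(free_src, perm))
        if all(adjacency_test(phi[a], phi[b]) for a, b in rec.edges):
            return phi
    return None


def _graphlet_adjacency_test(rec):
    return lambda a, b: bool(rec.masks[a] >> b & 1)


def lhs_coefficients(spec: ExtensionSpec, target_orbit: int) -> dict[int, int]:
    """Over-count coefficients f_p: for every orbit p of the same graphlet
    size, the number of (removable vertex z, extension set) pairs through
    which the right-hand-side enumeration reaches p's graphlet with the
    marked vertex fixed.  Includes the target orbit itself."""
    k = _record(atlas.graphlet_of_orbit(target_orbit)).k
    gp = _record(spec.reduced_graphlet_id)
    coeffs: dict[int, int] = {}
    for p in atlas.orbit_ids_for_size(k):
        gstar = _record(atlas.graphlet_of_orbit(p))
        members = next(
            cls for oid, cls in zip(gstar.node_orbit_ids, gstar.node_orbit_classes)
            if oid == p
        )
        xstar = min(members)
        f = 0
        for z in range(gstar.k):
            if z == xstar:
                continue
            keep = tuple(v for v in range(gstar.k) if v != z)
            sub = _induced_edges(gstar, keep)
            if len(sub) != len(gp.edges):
                continue
            try:
                got = atlas.identify(sub, marked=xstar)
            except atlas.IdentificationError:
                continue  # disconnected after removal
            if got != (gp.id, spec.marked_orbit):
                continue
            phi = find_embedding(
                gp.id, keep, _graphlet_adjacency_test(gstar),
                {spec.marked_vertex: xstar},
            )
            nz = set(gstar.adj[z])
            f += sum(
                1 for E in spec.extension_sets if all(phi[v] in nz for v in E)
            )
        if f:
            coeffs[p] = f
    return coeffs


def lhs_coefficients_edge(spec: ExtensionSpec, target_edge_orbit: int) -> dict[int, int]:
    """Edge-orbit variant of :func:`lhs_coefficients`."""
    k = _record(atlas.graphlet_of_edge_orbit(target_edge_orbit)).k
    gp = _record(spec.reduced_graphlet_id)
    a0, b0 = spec.marked_edge
    coeffs: dict[int, int] = {}
    for p in atlas.edge_orbit_ids_for_size(k):
        gstar = _record(atlas.graphlet_of_edge_orbit(p))
        members = next(
            cls for eoid, cls in zip(gstar.edge_orbit_ids, gstar.edge_orbit_classes)
            if eoid == p
        )
        ustar, vstar = min(members)
        f = 0
        for z in range(gstar.k):
            if z == ustar or z == vstar:
                continue
            keep = tuple(v for v in range(gstar.k) if v != z)
            sub = _induced_edges(gstar, keep)
            if len(sub) != len(gp.edges):
                continue
            try:
                got = atlas.identify_edge(sub, (ustar, vstar))
            except atlas.IdentificationError:
                continue
            if got != (gp.id, spec.marked_orbit):
                continue
            phi = None
            for pin in ({a0: ustar, b0: vstar}, {a0: vstar, b0: ustar}):
                phi = find_embedding(
                    gp.id, keep, _graphlet_adjacency_test(gstar), pin
                )
                if phi is not None:
                    break
            nz = set(gstar.adj[z])
            f += sum(
                1 for E in spec.extension_sets if all(phi[v] in nz for v in E)
            )
        if f:
            coeffs[p] = f
    return coeffs


def _orbit_members(rec, orbit_id: int) -> frozenset[int]:
    for oid, cls in zip(rec.node_orbit_ids, rec.node_orbit_classes):
        if oid == orbit_id:
            return cls
    raise OrbitCountError(f"orbit {orbit_id} not in G{rec.id}")  # pragma: no cover


def _check_equation(eq: OrbitEquation, target_edges: int, edge_mode: bool) -> None:
    of = atlas.graphlet_of_edge_orbit if edge_mode else atlas.graphlet_of_orbit
    if eq.lhs.get(eq.target_orbit, 0) < 1:  # pragma: no cover - derivation witness
        raise OrbitCountError(f"equation for orbit {eq.target_orbit} misses its target")
    for p in eq.lhs:
        if p != eq.target_orbit and len(_record(of(p)).edges) <= target_edges:
            raise OrbitCountError(  # pragma: no cover - derivation witness
                f"equation for orbit {eq.target_orbit} is not triangular at {p}"
            )


@lru_cache(maxsize=None)
def build_node_system(k: int) -> tuple[OrbitEquation, ...]:
    """One equation per k-node orbit except the clique orbit; includes the
    special 4-cycle equation when k = 4."""
    if k not in (4, 5):
        raise UnsupportedSizeError(f"equation systems are built for k in {{4, 5}}, got {k}")
    equations = []
    for i in atlas.orbit_ids_for_size(k):
        ga = _record(atlas.graphlet_of_orbit(i))
        x = min(_orbit_members(ga, i))
        special = False
        try:
            y = select_y(ga.id, x)
        except CompleteGraphletSignal:
            continue  # the clique orbit is enumerated directly
        except CycleSpecialSignal:
            y = min(ga.adj[x])
            special = True
        keep = tuple(v for v in range(ga.k) if v != y)
        gp_id, marked = atlas.identify(_induced_edges(ga, keep), marked=x)
        x0 = min(_orbit_members(_record(gp_id), marked))
        spec = extension_sets(gp_id, x0, ga.id, i)
        lhs = lhs_coefficients(spec, i)
        eq = OrbitEquation(i, lhs, spec, edge_mode=False, special_c4=special)
        _check_equation(eq, len(ga.edges), edge_mode=False)
        equations.append(eq)
    return tuple(equations)


@lru_cache(maxsize=None)
def build_edge_system(k: int) -> tuple[OrbitEquation, ...]:
    """Edge-orbit analogue of :func:`build_node_system`: the marked element is
    an edge (x_a, x_b); the removable node additionally avoids x_b."""
    if k not in (4, 5):
        raise UnsupportedSizeError(f"equation systems are built for k in {{4, 5}}, got {k}")
    equations = []
    for i in atlas.edge_orbit_ids_for_size(k):
        ga = _record(atlas.graphlet_of_edge_orbit(i))
        members = next(
            cls for eoid, cls in zip(ga.edge_orbit_ids, ga.edge_orbit_classes)
            if eoid == i
        )
        xa, xb = min(members)
        special = False
        try:
            y = select_y(ga.id, xa, forbidden=xb)
        except CompleteGraphletSignal:
            continue  # the clique edge orbit is enumerated directly
        except CycleSpecialSignal:
            y = min(v for v in ga.adj[xa] if v != xb)
            special = True
        keep = tuple(v for v in range(ga.k) if v != y)
        gp_id, marked = atlas.identify_edge(_induced_edges(ga, keep), (xa, xb))
        gp = _record(gp_id)
        me0 = min(
            next(
                cls for eoid, cls in zip(gp.edge_orbit_ids, gp.edge_orbit_classes)
                if eoid == marked
            )
        )
        spec = extension_sets_edge(gp_id, me0, ga.id, i)
        lhs = lhs_coefficients_edge(spec, i)
        eq = OrbitEquation(i, lhs, spec, edge_mode=True, special_c4=special)
        _check_equation(eq, len(ga.edges), edge_mode=True)
        equations.append(eq)
    return tuple(equations)


def system_to_json(equations: Iterable[OrbitEquation]) -> str:
    """Serialize a system for the ``--dump-equations`` snapshot."""
    payload = []
    for eq in equations:
        payload.append(
            {
                "target_orbit": eq.target_orbit,
                "edge_mode": eq.edge_mode,
                "special_c4": eq.special_c4,
                "lhs": {str(p): f for p, f in sorted(eq.lhs.items())},
                "reduced_graphlet": eq.rhs.reduced_graphlet_id,
                "marked_orbit": eq.rhs.marked_orbit,
                "marked_vertex": eq.rhs.marked_vertex,
                "marked_edge": list(eq.rhs.marked_edge) if eq.rhs.marked_edge else None,
                "extension_sets": [sorted(E) for E in eq.rhs.extension_sets],
                "corrections": list(eq.rhs.corrections),
            }
        )
    return json.dumps(payload, indent=1)
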