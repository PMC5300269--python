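"""Equation derivation: pinned published relations, removable-node
selection, constructive re-attachment checks and an independent
coefficient oracle."""

from __future__ import annotations

import json
from itertools import combinations

import networkx as nx
import pytest

from orbitcount import atlas, equations
from orbitcount.equations import (
    CompleteGraphletSignal,
    CycleSpecialSignal,
    build_edge_system,
    build_node_system,
    extension_sets,
    layer_decomposition,
    select_y,
    system_to_json,
)
from orbitcount.errors import UnsupportedSizeError


def _rec(gid):
    return atlas._RECORDS[gid]


def _nx_of(gid: int, extra_edges=()) -> nx.Graph:
    rec = _rec(gid)
    g = nx.Graph()
    g.add_nodes_from(range(rec.k))
    g.add_edges_from(rec.edges)
    g.add_edges_from(extra_edges)
    return g


# --------------------------------------------------------------------------
# pinned published relations


def test_equation_for_orbit_59_is_pinned():
    """The derived relation for orbit 59 reads
    o59 + 4*o65 + 2*o68 + 6*o70 = sum over diamonds with x in orbit 12."""
    eq = next(e for e in build_node_system(5) if e.target_orbit == 59)
    assert dict(eq.lhs) == {59: 1, 65: 4, 68: 2, 70: 6}
    assert eq.rhs.reduced_graphlet_id == 7
    assert eq.rhs.marked_orbit == 12
    assert len(eq.rhs.extension_sets) == 2
    assert eq.rhs.corrections == (1, 1)
    assert not eq.special_c4


def test_reduction_of_g24_lands_in_diamond_orbit_12():
    """Removing the selected node from G24 (x in orbit 59) leaves the
    diamond with x in orbit 12 — the tie-break reproduces the published
    derivation."""
    rec = _rec(24)
    x = min(v for o, cls in zip(rec.node_orbit_ids, rec.node_orbit_classes)
            if o == 59 for v in cls)
    y = select_y(24, x)
    keep = [v for v in range(rec.k) if v != y]
    sub = [e for e in rec.edges if e[0] in keep and e[1] in keep]
    assert atlas.identify(sub, marked=x) == (7, 12)


def test_c4_special_equation_is_pinned():
    """The 4-cycle orbit relation reads 2*o8 + 2*o12 = sum over induced
    3-paths at x of (c(x, x2) - 1)."""
    eq = next(e for e in build_node_system(4) if e.target_orbit == 8)
    assert eq.special_c4
    assert dict(eq.lhs) == {8: 2, 12: 2}
    assert eq.rhs.reduced_graphlet_id == 1  # the 3-path
    assert len(eq.rhs.extension_sets) == 1
    assert eq.rhs.corrections == (1,)
    # the single extension set joins the marked end to the far end
    (E,) = eq.rhs.extension_sets
    rec = _rec(1)
    assert eq.rhs.marked_vertex in E
    assert all(v not in rec.adj[eq.rhs.marked_vertex] for v in E - {eq.rhs.marked_vertex})


# --------------------------------------------------------------------------
# removable-node selection


def test_select_y_on_star_returns_a_leaf():
    rec = _rec(11)  # K_{1,4}
    centre = max(range(5), key=lambda v: len(rec.adj[v]))
    y = select_y(11, centre)
    assert len(rec.adj[y]) == 1


def test_select_y_signals():
    with pytest.raises(CompleteGraphletSignal):
        select_y(29, 0)  # K5: every vertex violates the degree condition
    with pytest.raises(CompleteGraphletSignal):
        select_y(8, 0)
    with pytest.raises(CycleSpecialSignal):
        select_y(5, 0)  # C4: the required vertex does not exist


def _valid_conditions(rec, y):
    d = len(rec.adj[y])
    if d > rec.k - 2:
        return False
    keep = set(range(rec.k)) - {y}
    g = nx.Graph([e for e in rec.edges if e[0] in keep and e[1] in keep])
    g.add_nodes_from(keep)
    if not nx.is_connected(g):
        return False
    if d == rec.k - 2:
        ng = nx.Graph()
        ng.add_nodes_from(rec.adj[y])
        ng.add_edges_from(
            (a, b) for a, b in combinations(sorted(rec.adj[y]), 2)
            if rec.masks[a] >> b & 1
        )
        if not nx.is_connected(ng):
            return False
    return True


@pytest.mark.parametrize("k", [4, 5])
def test_select_y_exists_for_every_graphlet_and_anchor(k):
    """Constructive form of the existence proof: for every non-complete,
    non-C4 graphlet and every choice of x (and forbidden endpoint in edge
    mode) the selected y satisfies all three conditions."""
    for g in atlas.enumerate_graphlets(k):
        rec = _rec(g.id)
        complete = len(g.edges) == k * (k - 1) // 2
        for x in range(k):
            if complete or g.id == 5:
                continue
            y = select_y(g.id, x)
            assert y != x
            assert _valid_conditions(rec, y)
            # layer rule: y is drawn from the farthest or next-to-farthest layer
            layers = layer_decomposition(g.id, x).layers
            assert y in layers[-1] or (len(layers) > 2 and y in layers[-2])
        for eo in atlas.edge_orbits(g):
            if complete or g.id == 5:
                continue
            xa, xb = min(eo.members)
            y = select_y(g.id, xa, forbidden=xb)
            assert y not in (xa, xb)
            assert _valid_conditions(rec, y)


# --------------------------------------------------------------------------
# extension sets and coefficients


def test_extension_sets_examples():
    # K_{k-1} extended to the k-clique: attach to everything, no correction
    spec = extension_sets(8, 0, 29, 72)
    assert spec.extension_sets == (frozenset(range(4)),)
    assert spec.corrections == (0,)
    # 3-path extended to C4 from an end vertex: attach to the marked end
    # and the far end; one common neighbour inside the path
    spec = extension_sets(1, 0, 5, 8)
    assert len(spec.extension_sets) == 1
    assert spec.corrections == (1,)


def _independent_reattachment_ok(eq) -> bool:
    """Re-attach a vertex along every extension set and verify with
    networkx that the target graphlet reappears with the marked element in
    the target orbit."""
    gp = _rec(eq.rhs.reduced_graphlet_id)
    if eq.edge_mode:
        target_gid = atlas.graphlet_of_edge_orbit(eq.target_orbit)
        members = next(
            eo.members for eo in atlas.edge_orbits(target_gid)
            if eo.id == eq.target_orbit
        )
    else:
        target_gid = atlas.graphlet_of_orbit(eq.target_orbit)
        members = next(
            o.members for o in atlas.node_orbits(target_gid)
            if o.id == eq.target_orbit
        )
    target = _nx_of(target_gid)
    new = gp.k
    for E in eq.rhs.extension_sets:
        g = _nx_of(gp.id, extra_edges=[(new, v) for v in E])
        if not nx.is_isomorphic(g, target):
            return False
        matcher = nx.algorithms.isomorphism.GraphMatcher(g, target)
        if eq.edge_mode:
            a0, b0 = eq.rhs.marked_edge
            ok = any(
                tuple(sorted((m[a0], m[b0]))) in members
                for m in matcher.isomorphisms_iter()
            )
        else:
            x0 = eq.rhs.marked_vertex
            ok = any(m[x0] in members for m in matcher.isomorphisms_iter())
        if not ok:
            return False
    return True


@pytest.mark.parametrize("k,mode", [(4, "node"), (5, "node"), (4, "edge"), (5, "edge")])
def test_every_extension_reconstructs_the_target(k, mode):
    system = build_node_system(k) if mode == "node" else build_edge_system(k)
    for eq in system:
        assert _independent_reattachment_ok(eq), f"orbit {eq.target_orbit}"


def _bruteforce_lhs(eq) -> dict[int, int]:
    """Independent coefficient oracle: enumerate (z, E) pairs directly with
    networkx isomorphism tests, never using the package's embedding search
    or identification keys."""
    gp = _rec(eq.rhs.reduced_graphlet_id)
    gp_nx = _nx_of(gp.id)
    k = gp.k + 1
    if eq.edge_mode:
        all_ids = atlas.edge_orbit_ids_for_size(k)
    else:
        all_ids = atlas.orbit_ids_for_size(k)
    coeffs: dict[int, int] = {}
    for p in all_ids:
        if eq.edge_mode:
            gstar_id = atlas.graphlet_of_edge_orbit(p)
            members = next(
                eo.members for eo in atlas.edge_orbits(gstar_id) if eo.id == p
            )
            marked = min(members)
        else:
            gstar_id = atlas.graphlet_of_orbit(p)
            members = next(
                o.members for o in atlas.node_orbits(gstar_id) if o.id == p
            )
            marked = (min(members),)
        gstar = _rec(gstar_id)
        gstar_nx = _nx_of(gstar_id)
        f = 0
        for z in range(gstar.k):
            if z in marked:
                continue
            keep = [v for v in range(gstar.k) if v != z]
            sub = gstar_nx.subgraph(keep)
            if not nx.is_connected(sub) or sub.number_of_edges() != gp_nx.number_of_edges():
                continue
            if not nx.is_isomorphic(sub, gp_nx):
                continue
            # the occurrence is enumerated only if the marked element sits in
            # the reduced graphlet's marked orbit
            sub_matcher = nx.algorithms.isomorphism.GraphMatcher(sub, gp_nx)
            if eq.edge_mode:
                gp_marked = next(
                    eo.members for eo in atlas.edge_orbits(gp.id)
                    if eo.id == eq.rhs.marked_orbit
                )
                a, b = marked
                if not any(
                    tuple(sorted((m[a], m[b]))) in gp_marked
                    for m in sub_matcher.isomorphisms_iter()
                ):
                    continue
            else:
                gp_marked = next(
                    o.members for o in atlas.node_orbits(gp.id)
                    if o.id == eq.rhs.marked_orbit
                )
                if not any(
                    m[marked[0]] in gp_marked for m in sub_matcher.isomorphisms_iter()
                ):
                    continue
            nz = set(gstar.adj[z])
            # enumerate candidate extension images directly in the subgraph:
            # S is valid if attaching a vertex on S rebuilds G_a with the
            # marked element in the target orbit
            target_nx = _nx_of(
                atlas.graphlet_of_edge_orbit(eq.target_orbit)
                if eq.edge_mode else atlas.graphlet_of_orbit(eq.target_orbit)
            )
            if eq.edge_mode:
                tmembers = next(
                    eo.members for eo in atlas.edge_orbits(
                        atlas.graphlet_of_edge_orbit(eq.target_orbit))
                    if eo.id == eq.target_orbit
                )
            else:
                tmembers = next(
                    o.members for o in atlas.node_orbits(
                        atlas.graphlet_of_orbit(eq.target_orbit))
                    if o.id == eq.target_orbit
                )
            # the marked element of G* must sit in G' in the reduced marked
            # orbit; S additionally must lie inside N(z)
            for r in range(1, len(keep) + 1):
                for S in combinations(keep, r):
                    if not set(S) <= nz:
                        continue
                    g = nx.Graph(sub)
                    g.add_edges_from(("new", v) for v in S)
                    if not nx.is_isomorphic(g, target_nx):
                        continue
                    matcher = nx.algorithms.isomorphism.GraphMatcher(g, target_nx)
                    if eq.edge_mode:
                        a, b = marked
                        if any(
                            tuple(sorted((m[a], m[b]))) in tmembers
                            for m in matcher.isomorphisms_iter()
                        ):
                            f += 1
                    else:
                        if any(m[marked[0]] in tmembers for m in matcher.isomorphisms_iter()):
                            f += 1
        if f:
            coeffs[p] = f
    return coeffs


@pytest.mark.parametrize(
    "k,mode,targets",
    [
        (4, "node", None),                      # the full 4-node system
        (5, "node", (15, 35, 49, 59, 62, 70)),  # spread over densities
        (4, "edge", None),
        (5, "edge", (13, 30, 54)),
    ],
)
def test_lhs_coefficients_match_bruteforce(k, mode, targets):
    """Coefficient symmetry check: Algorithm-style f_p equals a direct
    enumeration over all (z, extension) pairs via networkx isomorphisms."""
    system = build_node_system(k) if mode == "node" else build_edge_system(k)
    for eq in system:
        if targets is not None and eq.target_orbit not in targets:
            continue
        assert dict(eq.lhs) == _bruteforce_lhs(eq), f"orbit {eq.target_orbit}"


# --------------------------------------------------------------------------
# whole-system structure


@pytest.mark.parametrize(
    "k,mode,expected",
    [(4, "node", 10), (5, "node", 57), (4, "edge", 9), (5, "edge", 55)],
)
def test_system_sizes(k, mode, expected):
    system = build_node_system(k) if mode == "node" else build_edge_system(k)
    assert len(system) == expected


@pytest.mark.parametrize("k,mode", [(4, "node"), (5, "node"), (4, "edge"), (5, "edge")])
def test_triangularity(k, mode):
    """Every non-target term belongs to a graphlet with strictly more
    edges, so ordering by edge count solves the system by substitution."""
    system = build_node_system(k) if mode == "node" else build_edge_system(k)
    of = atlas.graphlet_of_edge_orbit if mode == "edge" else atlas.graphlet_of_orbit
    for eq in system:
        t_edges = len(_rec(of(eq.target_orbit)).edges)
        assert eq.lhs[eq.target_orbit] >= 1
        for p, f in eq.lhs.items():
            assert f >= 1
            if p != eq.target_orbit:
                assert len(_rec(of(p)).edges) > t_edges


def test_build_system_rejects_unsupported_k():
    with pytest.raises(UnsupportedSizeError):
        build_node_system(6)
    with pytest.raises(UnsupportedSizeError):
        build_edge_system(3)


def test_system_json_export_roundtrips():
    payload = json.loads(system_to_json(build_node_system(4)))
    assert len(payload) == 10
    entry = next(p for p in payload if p["target_orbit"] == 8)
    assert entry["special_c4"] is True
    assert entry["lhs"] == {"8": 2, "12": 2}
    for p in payload:
        assert {"target_orbit", "lhs", "reduced_graphlet", "extension_sets",
                "corrections"} <= set(p)
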