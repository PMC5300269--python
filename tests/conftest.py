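"""Shared fixtures and independent helper oracles for the test suite.

Helpers here deliberately avoid the package's enumeration and embedding
machinery: connectivity and isomorphism go through networkx, and subgraph
enumeration filters all C(n, k) subsets, so that engine results are checked
against genuinely independent computations.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pytest

from orbitcount import GeneratorSpec, HostGraph, generate


def nx_graph(h: HostGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(h.n))
    g.add_edges_from(h.edges)
    return g


def host_from_nx(g: nx.Graph) -> HostGraph:
    mapping = {v: i for i, v in enumerate(sorted(g.nodes(), key=repr))}
    return HostGraph(len(mapping), [(mapping[u], mapping[v]) for u, v in g.edges()])


def naive_connected_ksets(h: HostGraph, k: int) -> list[tuple[int, ...]]:
    """All connected k-vertex subsets by filtering every C(n, k) subset."""
    g = nx_graph(h)
    return [
        W
        for W in combinations(range(h.n), k)
        if nx.is_connected(g.subgraph(W))
    ]


def er(n: int, p: float, seed: int) -> HostGraph:
    return generate(GeneratorSpec("erdos_renyi", n, p=p, seed=seed))


@pytest.fixture
def c4() -> HostGraph:
    return generate(GeneratorSpec("cycle", 4))


@pytest.fixture
def p5() -> HostGraph:
    return generate(GeneratorSpec("path", 5))


@pytest.fixture
def k6() -> HostGraph:
    return generate(GeneratorSpec("clique", 6))


@pytest.fixture
def single_edge() -> HostGraph:
    return HostGraph(2, [(0, 1)])
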