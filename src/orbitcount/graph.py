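"""Host-graph container used by the counting engine and the oracle."""

from __future__ import annotations

from typing import Iterable, Sequence

from .errors import GraphInputError

__all__ = ["HostGraph"]


class HostGraph:
    """A simple undirected graph over vertices ``0..n-1``.

    Stores sorted adjacency lists plus per-vertex neighbour bitmasks, which
    give constant-time edge membership tests and fast set algebra on
    neighbourhoods (intersection and popcount on Python integers).  The
    input edge order is preserved because edge-orbit count matrices report
    one row per input edge.
    """

    __slots__ = ("n", "edges", "adj", "masks", "degrees", "edge_index")

    def __init__(self, n: int, edges: Iterable[Sequence[int]]):
        if n < 0:
            raise GraphInputError(f"vertex count must be nonnegative, got {n}")
        self.n = n
        edge_list: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        adj: list[list[int]] = [[] for _ in range(n)]
        for u, v in edges:
            if not (0 <= u < n and 0 <= v < n):
                raise GraphInputError(f"edge ({u}, {v}) out of range for n={n}")
            if u == v:
                raise GraphInputError(f"self-loop at vertex {u}")
            key = (u, v) if u < v else (v, u)
            if key in seen:
                raise GraphInputError(f"duplicate edge ({u}, {v})")
            seen.add(key)
            edge_list.append((u, v))
            adj[u].append(v)
            adj[v].append(u)
        self.edges = tuple(edge_list)
        self.adj = tuple(tuple(sorted(nbrs)) for nbrs in adj)
        self.masks = tuple(sum(1 << w for w in nbrs) for nbrs in self.adj)
        self.degrees = tuple(len(nbrs) for nbrs in self.adj)
        self.edge_index = {
            (min(u, v), max(u, v)): i for i, (u, v) in enumerate(self.edges)
        }

    @property
    def e(self) -> int:
        return len(self.edges)

    @property
    def max_degree(self) -> int:
        return max(self.degrees, default=0)

    def has_edge(self, u: int, v: int) -> bool:
        return bool(self.masks[u] >> v & 1)

    def __repr__(self) -> str:  # pragma: no cover
        return f"HostGraph(n={self.n}, e={self.e})"
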