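"""Brute-force ground truth: enumerate every connected induced k-subgraph
and tally node orbits, edge orbits and graphlet totals by direct
classification.  A test instrument, deliberately independent of the
equation machinery: no common-neighbour tables, no clique shortcut, no
triangular solve."""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

from . import atlas
from .counting import OrbitCountMatrix, _connected_msets, _subgraph_profile
from .errors import OracleCapError, UnsupportedSizeError
from .graph import HostGraph

__all__ = ["OracleResult", "oracle_counts", "DEFAULT_CAP"]

#: Refuse instances whose all-subsets projection exceeds this many sets.
DEFAULT_CAP = 10_000_000


@dataclass(frozen=True)
class OracleResult:
    node_counts: OrbitCountMatrix
    edge_counts: OrbitCountMatrix
    graphlet_totals: dict[int, int]


def oracle_counts(h: HostGraph, k: int, cap: int = DEFAULT_CAP) -> OracleResult:
    """Exhaustive orbit counts for graphlets of sizes 2..k (k in 2..5).

    Every connected induced subset is visited exactly once via anchored
    growth; classification uses the atlas identification keys.  Refuses
    hosts where C(n, k) exceeds ``cap``.
    """
    if not 2 <= k <= 5:
        raise UnsupportedSizeError(f"oracle supports k in 2..5, got {k}")
    if comb(h.n, k) > cap:
        raise OracleCapError(
            f"C({h.n}, {k}) = {comb(h.n, k)} exceeds the oracle cap {cap}"
        )
    ncols = atlas.orbit_column_count(k) if h.n else 0
    ecols = atlas.edge_orbit_column_count(k)
    node_rows = [[0] * ncols for _ in range(h.n)]
    edge_rows = [[0] * ecols for _ in range(h.e)]
    totals: dict[int, int] = {}
    masks = h.masks
    for m in range(2, k + 1):
        for W in _connected_msets(h, m):
            rec, vkeys, _ = _subgraph_profile(h, W)
            totals[rec.id] = totals.get(rec.id, 0) + 1
            for i, v in enumerate(W):
                node_rows[v][rec.orbit_of_vkey[vkeys[i]]] += 1
            for i in range(m):
                for j in range(i + 1, m):
                    u, v = W[i], W[j]
                    if masks[u] >> v & 1:
                        ek = tuple(sorted((vkeys[i], vkeys[j])))
                        row = h.edge_index[(u, v) if u < v else (v, u)]
                        edge_rows[row][rec.edge_orbit_of_ekey[ek]] += 1
    return OracleResult(
        node_counts=OrbitCountMatrix("node", k, tuple(tuple(r) for r in node_rows)),
        edge_counts=OrbitCountMatrix("edge", k, tuple(tuple(r) for r in edge_rows)),
        graphlet_totals=totals,
    )
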