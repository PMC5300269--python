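"""Reading edge-list graphs and writing orbit-count matrices.

The edge-list format is the one used throughout graphlet-counting
pipelines: a header line ``n e`` followed by ``e`` lines ``u v`` with
0-based vertex ids.  Parsing is whitespace-tolerant; comments are not
supported.
"""

from __future__ import annotations

from typing import TextIO

from .errors import GraphInputError
from .graph import HostGraph

__all__ = ["read_graph", "write_graph", "write_counts"]


def read_graph(stream: TextIO) -> HostGraph:
    """Parse an edge-list document into a validated :class:`HostGraph`.

    Raises :class:`GraphInputError` naming the offending line for a
    malformed header, out-of-range ids, self-loops and duplicate edges.
    """
    lines = [ln for ln in (raw.strip() for raw in stream) if ln]
    if not lines:
        raise GraphInputError("line 1: missing 'n e' header")
    head = lines[0].split()
    if len(head) != 2:
        raise GraphInputError(f"line 1: header must be 'n e', got {lines[0]!r}")
    try:
        n, e = int(head[0]), int(head[1])
    except ValueError:
        raise GraphInputError(f"line 1: header must be two integers, got {lines[0]!r}") from None
    if n < 0 or e < 0:
        raise GraphInputError("line 1: n and e must be nonnegative")
    if len(lines) - 1 != e:
        raise GraphInputError(
            f"header declares {e} edges but {len(lines) - 1} edge lines follow"
        )
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != 2:
            raise GraphInputError(f"line {lineno}: expected 'u v', got {ln!r}")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError:
            raise GraphInputError(f"line {lineno}: expected two integers, got {ln!r}") from None
        if not (0 <= u < n and 0 <= v < n):
            raise GraphInputError(f"line {lineno}: vertex id out of range 0..{n - 1}")
        if u == v:
            raise GraphInputError(f"line {lineno}: self-loop at vertex {u}")
        key = (u, v) if u < v else (v, u)
        if key in seen:
            raise GraphInputError(f"line {lineno}: duplicate edge {u} {v}")
        seen.add(key)
        edges.append((u, v))
    return HostGraph(n, edges)


def write_graph(h: HostGraph, stream: TextIO) -> None:
    """Write a host graph in the edge-list format (inverse of :func:`read_graph`)."""
    stream.write(f"{h.n} {h.e}\n")
    for u, v in h.edges:
        stream.write(f"{u} {v}\n")


def write_counts(matrix, stream: TextIO) -> None:
    """Write an orbit-count matrix: one space-separated integer row per line."""
    rows = matrix.rows if hasattr(matrix, "rows") else matrix
    for row in rows:
        stream.write(" ".join(map(str, row)))
        stream.write("\n")
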