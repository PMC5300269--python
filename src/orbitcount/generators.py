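"""Deterministic graph generators for tests, demos and benchmarks.

Random graphs use :class:`random.Random` (Mersenne Twister), whose stream
for a fixed seed is stable across Python versions and platforms, so a
``GeneratorSpec`` identifies one graph forever.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import GraphInputError
from .graph import HostGraph

__all__ = ["GeneratorSpec", "generate", "FAMILIES"]

FAMILIES = ("erdos_renyi", "path", "cycle", "star", "clique", "barbell")


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one deterministic graph.

    ``p`` is the independent edge probability and is used by the
    ``erdos_renyi`` family only; ``seed`` likewise.
    """

    family: str
    n: int
    p: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise GraphInputError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n < 1:
            raise GraphInputError(f"vertex count must be >= 1, got {self.n}")
        if self.family == "erdos_renyi":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise GraphInputError("erdos_renyi requires edge probability p in [0, 1]")
        if self.family == "cycle" and self.n < 3:
            raise GraphInputError("a cycle needs at least 3 vertices")
        if self.family == "barbell" and self.n < 4:
            raise GraphInputError("a barbell needs at least 4 vertices")


def generate(spec: GeneratorSpec) -> HostGraph:
    """Build the graph described by ``spec``; identical specs give identical graphs."""
    n = spec.n
    if spec.family == "erdos_renyi":
        rng = random.Random(spec.seed)
        edges = [
            (u, v)
            for u in range(n)
            for v in range(u + 1, n)
            if rng.random() < spec.p
        ]
    elif spec.family == "path":
        edges = [(i, i + 1) for i in range(n - 1)]
    elif spec.family == "cycle":
        edges = [(i, (i + 1) % n) for i in range(n)]
    elif spec.family == "star":
        edges = [(0, i) for i in range(1, n)]
    elif spec.family == "clique":
        edges = [(u, v) for u in range(n) for v in range(u + 1, n)]
    else:  # barbell: two cliques joined by a single bridge edge
        m = n // 2
        left = [(u, v) for u in range(m) for v in range(u + 1, m)]
        right = [(u, v) for u in range(m, n) for v in range(u + 1, n)]
        edges = left + right + [(m - 1, m)]
    return HostGraph(n, edges)
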