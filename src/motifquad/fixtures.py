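"""Deterministic generators for test graphs with known census answers.

Analytic kinds (path, cycle, star, complete) come with closed-form
census totals; ER kinds draw each possible arc independently; the
power-law kind emulates the shape of sparse transcription/metabolic
networks — a few hundred vertices, mean degree around 2-3, heavy-tailed
degree distribution — which is where leaf memoization pays off most
(many subgraphs, few isomorphism classes).

All randomness flows from the explicit ``seed``; there is no global
random state.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Optional

from .graph import Graph

KINDS = ("path", "cycle", "star", "complete",
         "er_directed", "er_undirected", "powerlaw_directed")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic graph.

    kind:
        One of :data:`KINDS`.
    n:
        Vertex count.
    directed:
        Orientation for the analytic kinds (ER/power-law kinds encode
        it in their name).
    p:
        Arc probability for the ER kinds.
    mean_degree, exponent:
        Power-law kind: target mean out-degree and tail exponent of the
        attachment weights.
    seed:
        Seed for the random kinds.
    """

    kind: str
    n: int
    directed: bool = True
    p: Optional[float] = None
    mean_degree: float = 2.5
    exponent: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.kind.startswith("er_") and not (self.p is not None and 0 <= self.p <= 1):
            raise ValueError("er_* kinds need an arc probability p in [0, 1]")


def generate(spec: FixtureSpec) -> Graph:
    """Build the graph described by ``spec`` (deterministic per spec)."""
    n = spec.n
    if spec.kind == "path":
        return Graph(n, [(i, i + 1) for i in range(n - 1)], directed=spec.directed)
    if spec.kind == "cycle":
        if n < 3:
            raise ValueError("cycle needs n >= 3")
        return Graph(n, [(i, (i + 1) % n) for i in range(n)], directed=spec.directed)
    if spec.kind == "star":
        if n < 2:
            raise ValueError("star needs n >= 2")
        return Graph(n, [(0, i) for i in range(1, n)], directed=spec.directed)
    if spec.kind == "complete":
        arcs = [(i, j) for i in range(n) for j in range(n)
                if i != j and (spec.directed or i < j)]
        return Graph(n, arcs, directed=spec.directed)
    if spec.kind == "er_directed":
        rng = random.Random(spec.seed)
        arcs = [(i, j) for i in range(n) for j in range(n)
                if i != j and rng.random() < spec.p]
        return Graph(n, arcs, directed=True)
    if spec.kind == "er_undirected":
        rng = random.Random(spec.seed)
        arcs = [(i, j) for i in range(n) for j in range(i + 1, n)
                if rng.random() < spec.p]
        return Graph(n, arcs, directed=False)
    if spec.kind == "powerlaw_directed":
        return _powerlaw_directed(spec)
    raise AssertionError(spec.kind)


def _powerlaw_directed(spec: FixtureSpec) -> Graph:
    """Sparse directed graph with heavy-tailed degrees.

    Both arc endpoints are drawn from Zipf-like weights
    ``(rank+1)^(-1/(exponent-1))``, which yields a degree tail with
    exponent about ``spec.exponent``; arcs are rejection-sampled to
    keep the graph simple.
    """
    rng = random.Random(spec.seed)
    n = spec.n
    target_arcs = round(spec.mean_degree * n)
    alpha = 1.0 / (spec.exponent - 1.0)
    weights = [(i + 1) ** (-alpha) for i in range(n)]
    cum = list(_cumsum(weights))
    total = cum[-1]

    def draw() -> int:
        x = rng.random() * total
        lo, hi = 0, n - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if cum[mid] < x:
                lo = mid + 1
            else:
                hi = mid
        return lo

    arcs: set[tuple[int, int]] = set()
    max_tries = 50 * target_arcs
    tries = 0
    while len(arcs) < target_arcs and tries < max_tries:
        tries += 1
        u, w = draw(), draw()
        if u == w:
            continue
        arcs.add((u, w))
    return Graph(n, sorted(arcs), directed=True)


def _cumsum(xs):
    s = 0.0
    for x in xs:
        s += x
        yield s


def known_census(spec: FixtureSpec, k: int) -> tuple[int, int]:
    """Closed-form ``(subgraph count, class count)`` for analytic kinds.

    path: n-k+1 windows, one class; cycle (n > k): n windows, one
    class; complete: C(n, k), one class; star: C(n-1, k-1), one class.
    """
    n = spec.n
    if k < 2 or k > n:
        raise ValueError(f"k={k} outside 2..n={n}")
    if spec.kind == "path":
        return (n - k + 1, 1)
    if spec.kind == "cycle":
        if n <= k:
            raise ValueError("closed form requires n > k for cycles")
        return (n, 1)
    if spec.kind == "complete":
        return (math.comb(n, k), 1)
    if spec.kind == "star":
        return (math.comb(n - 1, k - 1), 1)
    raise ValueError(f"no closed-form census for kind {spec.kind!r}")
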