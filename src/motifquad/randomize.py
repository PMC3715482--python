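"""Degree-preserving null-model generation by Markov-chain edge swaps.

The null model rewires the input network by repeated switch moves: two
arcs ``a->b`` and ``c->d`` exchange targets to become ``a->d`` and
``c->b``.  Every accepted move preserves each vertex's in- and
out-degree exactly (degree sequence, for undirected graphs); moves that
would create a self-loop or a duplicate arc are rejected but still
consume one attempt, as is standard for the switching chain.  The
number of attempts is ``ceil(swaps_per_edge * edge count)`` with a
default of 3 swaps per edge.

With ``preserve_reciprocal`` (the default for directed graphs, in the
FANMOD lineage of motif null models) mutual arc pairs are swapped only
with mutual pairs and single arcs only with single arcs, so the count
of reciprocal connections is conserved as well.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .graph import Graph


@dataclass
class SwapConfig:
    """Parameters of the switching chain.

    swaps_per_edge:
        Attempted switches per edge (default 3).
    preserve_reciprocal:
        Conserve the number of mutual arc pairs (directed graphs only).
    seed:
        Base seed; ensemble member ``i`` uses ``seed + i``.
    """

    swaps_per_edge: float = 3.0
    preserve_reciprocal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swaps_per_edge <= 0:
            raise ValueError("swaps_per_edge must be positive")


def randomize(g: Graph, cfg: SwapConfig | None = None) -> Graph:
    """One degree-preserving randomization of ``g``.

    Graphs admitting no valid switch (a single edge, a directed
    3-cycle, a complete graph, ...) come back as identical copies:
    every attempt is rejected.
    """
    cfg = cfg or SwapConfig()
    rng = random.Random(cfg.seed)
    if g.directed:
        return _randomize_directed(g, cfg, rng)
    return _randomize_undirected(g, cfg, rng)


def generate_ensemble(g: Graph, r: int, cfg: SwapConfig | None = None) -> list[Graph]:
    """``r`` independent randomizations with per-network derived seeds."""
    if r < 0:
        raise ValueError("ensemble size must be nonnegative")
    cfg = cfg or SwapConfig()
    out = []
    for i in range(r):
        member_cfg = SwapConfig(swaps_per_edge=cfg.swaps_per_edge,
                                preserve_reciprocal=cfg.preserve_reciprocal,
                                seed=cfg.seed + i)
        out.append(randomize(g, member_cfg))
    return out


def _randomize_directed(g: Graph, cfg: SwapConfig, rng: random.Random) -> Graph:
    arcs = list(g.arcs())
    arc_set = set(arcs)
    n_arcs = len(arcs)
    if n_arcs < 2:
        return g.copy()
    pos = {a: i for i, a in enumerate(arcs)}
    attempts = math.ceil(cfg.swaps_per_edge * n_arcs)

    def replace(old: tuple[int, int], new: tuple[int, int]) -> None:
        i = pos.pop(old)
        arcs[i] = new
        pos[new] = i
        arc_set.discard(old)
        arc_set.add(new)

    for _ in range(attempts):
        i = rng.randrange(n_arcs)
        j = rng.randrange(n_arcs)
        if i == j:
            continue
        a, b = arcs[i]
        c, d = arcs[j]
        if cfg.preserve_reciprocal:
            mut_i = (b, a) in arc_set
            mut_j = (d, c) in arc_set
            if mut_i != mut_j:
                continue  # mutual pairs trade only with mutual pairs
            if mut_i:
                # swap whole reciprocal pairs: a<->b, c<->d  =>  a<->d, c<->b
                if a == d or c == b:
                    continue
                if ((a, d) in arc_set or (d, a) in arc_set
                        or (c, b) in arc_set or (b, c) in arc_set):
                    continue
                replace((a, b), (a, d))
                replace((b, a), (d, a))
                replace((c, d), (c, b))
                replace((d, c), (b, c))
                continue
            # two single arcs; the new arcs must stay single
            if a == d or c == b:
                continue
            if ((a, d) in arc_set or (c, b) in arc_set
                    or (d, a) in arc_set or (b, c) in arc_set):
                continue
            replace((a, b), (a, d))
            replace((c, d), (c, b))
        else:
            if a == d or c == b:
                continue
            if (a, d) in arc_set or (c, b) in arc_set:
                continue
            replace((a, b), (a, d))
            replace((c, d), (c, b))

    return Graph(g.n_vertices, arcs, directed=True)


def _randomize_undirected(g: Graph, cfg: SwapConfig, rng: random.Random) -> Graph:
    edges = sorted({(min(u, w), max(u, w)) for u, w in g.arcs()})
    edge_set = set(edges)
    n_edges = len(edges)
    if n_edges < 2:
        return g.copy()
    pos = {e: i for i, e in enumerate(edges)}
    attempts = math.ceil(cfg.swaps_per_edge * n_edges)

    def norm(u: int, w: int) -> tuple[int, int]:
        return (u, w) if u < w else (w, u)

    def replace(old: tuple[int, int], new: tuple[int, int]) -> None:
        i = pos.pop(old)
        edges[i] = new
        pos[new] = i
        edge_set.discard(old)
        edge_set.add(new)

    for _ in range(attempts):
        i = rng.randrange(n_edges)
        j = rng.randrange(n_edges)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # one of the two re-pairings, chosen uniformly
        if rng.random() < 0.5:
            c, d = d, c
        if a == d or b == c:
            continue
        new1, new2 = norm(a, d), norm(b, c)
        if new1 in edge_set or new2 in edge_set:
            continue
        replace((a, b) if (a, b) in pos else norm(a, b), new1)
        replace(norm(c, d), new2)

    return Graph(g.n_vertices, edges, directed=False)
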