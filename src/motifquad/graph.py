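"""Simple-graph container, edge-list I/O and the four-symbol edge code.

Networks are stored as vertex-indexed adjacency sets over contiguous
integer ids ``0..n-1``.  Directed and undirected graphs share one
representation: an undirected edge is stored as two symmetric arcs.
Alongside the adjacency sets the graph keeps per-vertex neighbour
bitmasks (arbitrary-precision ints), which is what makes the pure-Python
subgraph enumeration fast enough for networks with millions of induced
subgraphs.

The :func:`edge_symbol` code is the alphabet of the quaternary tree:
for a previously added subgraph vertex ``u`` and a newly added vertex
``w`` it reports ``2`` (mutual connection), ``1`` (only ``w -> u``),
``-1`` (only ``u -> w``) or ``0`` (no connection).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

logger = logging.getLogger(__name__)

#: The four edge-pattern symbols, in child-slot order.
EDGE_SYMBOLS = (-1, 0, 1, 2)

#: Fixed symbol -> child-slot index map of the quaternary tree.
SYMBOL_SLOT = {-1: 0, 0: 1, 1: 2, 2: 3}

#: Inverse of :data:`SYMBOL_SLOT`.
SLOT_SYMBOL = {slot: sym for sym, slot in SYMBOL_SLOT.items()}


class GraphError(ValueError):
    """Malformed input or an operation violating a graph invariant."""


class Graph:
    """A simple directed or undirected graph on vertices ``0..n-1``.

    Parameters
    ----------
    n_vertices:
        Number of vertices.
    arcs:
        Iterable of ``(u, w)`` pairs.  For an undirected graph each pair
        is inserted in both orientations.  Self-loops and duplicates are
        rejected here; use :func:`remove_self_loops` /
        :func:`load_edge_list` for tolerant preprocessing.
    directed:
        Orientation flag.  Undirected graphs are stored symmetrically.
    """

    __slots__ = ("n_vertices", "directed", "out_adj", "in_adj",
                 "_out_masks", "_in_masks", "_adj_masks")

    def __init__(self, n_vertices: int, arcs: Iterable[tuple[int, int]] = (),
                 directed: bool = True) -> None:
        if n_vertices < 0:
            raise GraphError("vertex count must be nonnegative")
        self.n_vertices = n_vertices
        self.directed = directed
        self.out_adj: list[set[int]] = [set() for _ in range(n_vertices)]
        self.in_adj: list[set[int]]
        if directed:
            self.in_adj = [set() for _ in range(n_vertices)]
        else:
            self.in_adj = self.out_adj
        self._out_masks: list[int] | None = None
        self._in_masks: list[int] | None = None
        self._adj_masks: list[int] | None = None
        for u, w in arcs:
            self.add_arc(u, w)

    # -- construction -------------------------------------------------

    def add_arc(self, u: int, w: int) -> None:
        """Insert arc ``u -> w`` (both orientations when undirected)."""
        self._check_vertex(u)
        self._check_vertex(w)
        if u == w:
            raise GraphError(f"self-loop {u}->{w} not allowed in a simple graph")
        self.out_adj[u].add(w)
        self.in_adj[w].add(u)
        if not self.directed:
            self.out_adj[w].add(u)
            self.in_adj[u].add(w)
        self._out_masks = self._in_masks = self._adj_masks = None

    def _check_vertex(self, v: int) -> None:
        if not 0 <= v < self.n_vertices:
            raise GraphError(f"vertex {v} outside 0..{self.n_vertices - 1}")

    # -- queries ------------------------------------------------------

    def has_arc(self, u: int, w: int) -> bool:
        return w in self.out_adj[u]

    def arcs(self) -> Iterator[tuple[int, int]]:
        """All stored arcs; an undirected edge appears in both orientations."""
        for u in range(self.n_vertices):
            for w in sorted(self.out_adj[u]):
                yield (u, w)

    @property
    def n_arcs(self) -> int:
        """Number of stored arcs (undirected edges count twice)."""
        return sum(len(s) for s in self.out_adj)

    @property
    def n_edges(self) -> int:
        """Number of arcs for directed graphs, of edges for undirected."""
        return self.n_arcs if self.directed else self.n_arcs // 2

    def neighbors(self, v: int) -> set[int]:
        """Open neighbourhood: union of in- and out-neighbours."""
        if self.directed:
            return self.out_adj[v] | self.in_adj[v]
        return set(self.out_adj[v])

    # -- bitmask views (lazily built, used by the enumerator) ---------

    def _build_masks(self) -> None:
        out = [0] * self.n_vertices
        inn = [0] * self.n_vertices
        for u in range(self.n_vertices):
            m = 0
            for w in self.out_adj[u]:
                m |= 1 << w
                inn[w] |= 1 << u
            out[u] = m
        self._out_masks = out
        self._in_masks = out if not self.directed else inn
        self._adj_masks = [out[v] | self._in_masks[v] for v in range(self.n_vertices)]

    @property
    def out_masks(self) -> list[int]:
        if self._out_masks is None:
            self._build_masks()
        return self._out_masks  # type: ignore[return-value]

    @property
    def in_masks(self) -> list[int]:
        if self._in_masks is None:
            self._build_masks()
        return self._in_masks  # type: ignore[return-value]

    @property
    def adj_masks(self) -> list[int]:
        """Per-vertex mask of the union in/out neighbourhood."""
        if self._adj_masks is None:
            self._build_masks()
        return self._adj_masks  # type: ignore[return-value]

    # -- misc ---------------------------------------------------------

    def copy(self) -> "Graph":
        g = Graph(self.n_vertices, directed=self.directed)
        for u in range(self.n_vertices):
            for w in self.out_adj[u]:
                g.out_adj[u].add(w)
                g.in_adj[w].add(u)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return (self.n_vertices == other.n_vertices
                and self.directed == other.directed
                and self.out_adj == other.out_adj)

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return f"Graph(n={self.n_vertices}, {kind}, edges={self.n_edges})"


def load_edge_list(path: Union[str, Path], directed: bool = True) -> Graph:
    """Read a whitespace-separated integer edge list.

    The dialect matches common motif-tool inputs: one ``src dst`` pair
    per non-empty line, ``#`` / ``%`` comment lines, and an optional
    third column (e.g. a weight) that is ignored.  Vertex ids are
    remapped to ``0..n-1`` in order of first appearance.  Self-loops
    and duplicate arcs are dropped with a logged count.

    Raises
    ------
    GraphError
        On a malformed line (named by line number) or an empty file.
    """
    path = Path(path)
    ids: dict[int, int] = {}
    raw_arcs: list[tuple[int, int]] = []
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped[0] in "#%":
                continue
            parts = stripped.split()
            if len(parts) < 2:
                raise GraphError(f"{path}:{lineno}: expected 'src dst', got {stripped!r}")
            try:
                src, dst = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise GraphError(f"{path}:{lineno}: non-integer vertex id in {stripped!r}") from exc
            for raw in (src, dst):
                if raw not in ids:
                    ids[raw] = len(ids)
            if src == dst:
                n_loops += 1
                continue
            raw_arcs.append((ids[src], ids[dst]))

    if not ids:
        raise GraphError(f"{path}: empty edge list")

    g = Graph(len(ids), directed=directed)
    n_dup = 0
    for u, w in raw_arcs:
        if g.has_arc(u, w):
            n_dup += 1
            continue
        g.add_arc(u, w)
    if n_loops or n_dup:
        logger.info("%s: dropped %d self-loop(s) and %d duplicate arc(s)",
                    path, n_loops, n_dup)
    return g


def write_edge_list(g: Graph, path: Union[str, Path]) -> None:
    """Write one ``src dst`` pair per line using the remapped ids.

    Undirected edges are written once, as ``min max``.
    """
    with open(path, "w") as fh:
        seen: set[tuple[int, int]] = set()
        for u, w in g.arcs():
            if not g.directed:
                key = (min(u, w), max(u, w))
                if key in seen:
                    continue
                seen.add(key)
                u, w = key
            fh.write(f"{u} {w}\n")


def remove_self_loops(g: Graph) -> Graph:
    """Return a copy of ``g`` with all arcs ``(v, v)`` deleted.

    Vertex count is unchanged; idempotent.  (``Graph`` built through the
    public constructor never holds loops, but graphs assembled from raw
    adjacency may.)
    """
    out = Graph(g.n_vertices, directed=g.directed)
    n_loops = 0
    for u in range(g.n_vertices):
        for w in g.out_adj[u]:
            if u == w:
                n_loops += 1
                continue
            out.out_adj[u].add(w)
            out.in_adj[w].add(u)
    if n_loops:
        logger.info("removed %d self-loop arc(s)", n_loops)
    return out


def edge_symbol(g: Graph, u: int, w: int) -> int:
    """Edge-pattern symbol between existing vertex ``u`` and new vertex ``w``.

    Returns ``2`` if both arcs are present, ``1`` if only ``w -> u``,
    ``-1`` if only ``u -> w`` and ``0`` if neither.  For undirected
    graphs only ``0`` and ``2`` can occur.
    """
    if u == w:
        raise GraphError("edge symbol undefined for u == w")
    uw = g.has_arc(u, w)
    wu = g.has_arc(w, u)
    if uw and wu:
        return 2
    if wu:
        return 1
    if uw:
        return -1
    return 0
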