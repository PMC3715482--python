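"""ESU enumeration of connected induced k-subgraphs, fused with the tree.

The enumerator visits every connected induced k-vertex subgraph exactly
once: each subgraph is discovered from its minimum vertex ``v`` (the
root of the ESU call), and extension candidates are restricted to
vertices ``> v`` drawn from the exclusive neighbourhood of the vertex
just added.  As each vertex joins the growing subgraph the quaternary
tree is descended in lock-step, so when the subgraph reaches size k the
current tree node already is the leaf encoding its arrival-order edge
pattern, and classification is a cached pointer lookup for all but the
first subgraph per leaf.

Candidate vertices are drawn in ascending id order rather than in a
random order; the multiset of visited subgraphs — hence the census —
is identical either way, and deterministic order makes runs
reproducible.

``brute_force_census`` is the independent oracle: enumerate all
C(n, k) vertex subsets, keep the connected ones, canonically label each
one directly.  It shares no code path with the ESU/tree census beyond
the labeling routine itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .graph import Graph, GraphError
from .canonical import ClassRegistry, canonical_label, induced_adjacency
from .quattree import NOVEL_CLASS, QuatNode, QuatTree

logger = logging.getLogger(__name__)

# child-slot from the (u->w, w->u) bit pair: 00 -> '0', 01 -> '1',
# 10 -> '-1', 11 -> '2' under the fixed map {-1:0, 0:1, 1:2, 2:3}
_SLOT_FROM_BITS = (1, 2, 0, 3)

_PROGRESS_EVERY = 10 ** 6


@dataclass
class Census:
    """Per-class subgraph counts for one network.

    ``excluded`` counts subgraphs whose isomorphism class is absent
    from a frozen registry (random-network census only).
    """

    counts: dict[int, int] = field(default_factory=dict)
    total: int = 0
    excluded: int = 0
    canonical_calls: int = 0
    new_leaves: int = 0
    #: populated only with ``collect_leaf_members=True``
    leaf_members: Optional[dict[int, list[tuple[int, ...]]]] = None
    #: populated only with ``record_vertex_sets=True``
    vertex_sets: Optional[list[tuple[int, ...]]] = None

    def label_counts(self, registry: ClassRegistry) -> dict[str, int]:
        """Counts keyed by canonical label instead of class id."""
        return {registry.record(cid).canonical_label: c
                for cid, c in self.counts.items()}


def exclusive_neighborhood(g: Graph, w: int, subgraph_vertices) -> set[int]:
    """Neighbours of ``w`` neither in nor adjacent to the subgraph.

    Neighbourhood is the union of in- and out-neighbours.
    """
    subg = set(subgraph_vertices)
    if w in subg:
        raise GraphError("w must lie outside the subgraph")
    closed = set(subg)
    for u in subg:
        closed |= g.neighbors(u)
    return g.neighbors(w) - closed


def census(g: Graph, k: int,
           tree: Optional[QuatTree] = None,
           registry: Optional[ClassRegistry] = None,
           network: str = "original",
           collect_leaf_members: bool = False,
           record_vertex_sets: bool = False) -> Census:
    """Count all connected induced k-subgraphs of ``g`` by class.

    ``tree`` and ``registry`` persist across calls within one motif
    run: pass the same objects for the original network and every
    random network.  Freeze the registry (``registry.freeze()``)
    before random censuses so novel classes are excluded rather than
    created; the tree keeps growing regardless.
    """
    if k < 2 or k > g.n_vertices:
        raise GraphError(f"motif size k={k} outside 2..n={g.n_vertices}")
    if tree is None:
        tree = QuatTree()
    if registry is None:
        registry = ClassRegistry()

    n = g.n_vertices
    out = g.out_masks
    adj = g.adj_masks
    slot_from_bits = _SLOT_FROM_BITS
    node_cls = QuatNode
    result = Census()
    counts = result.counts
    calls_before = registry.canonical_calls
    frozen = registry.frozen
    leaf_members: dict[int, list[tuple[int, ...]]] = {}
    vertex_sets: list[tuple[int, ...]] = []
    state = {"total": 0, "excluded": 0, "new_leaves": 0}

    def resolve(leaf: QuatNode, vertices: tuple[int, ...]) -> None:
        ptr = leaf.pointer
        if ptr is None:
            label = canonical_label(induced_adjacency(g, vertices))
            registry.canonical_calls += 1
            state["new_leaves"] += 1
            cid = registry.classify(label)
            leaf.pointer = NOVEL_CLASS if cid is None else cid
            ptr = leaf.pointer
        if collect_leaf_members:
            leaf_members.setdefault(id(leaf), []).append(vertices)
        if record_vertex_sets:
            vertex_sets.append(vertices)
        state["total"] += 1
        if state["total"] % _PROGRESS_EVERY == 0:
            logger.info("census: %d subgraphs so far", state["total"])
        if ptr == NOVEL_CLASS:
            state["excluded"] += 1
            return
        counts[ptr] = counts.get(ptr, 0) + 1

    def extend(subg: tuple[int, ...], ext: int, closed: int,
               v_high_mask: int, node: QuatNode) -> None:
        last = len(subg) == k - 1
        m = ext
        while m:
            lsb = m & -m
            w = lsb.bit_length() - 1
            m ^= lsb
            # descend one level per subgraph vertex, creating children
            cur = node
            out_w = out[w]
            for u in subg:
                slot = slot_from_bits[(((out[u] >> w) & 1) << 1) | ((out_w >> u) & 1)]
                child = cur.children[slot]
                if child is None:
                    child = node_cls(depth=cur.depth + 1)
                    cur.children[slot] = child
                cur = child
            if last:
                resolve(cur, subg + (w,))
            else:
                new = adj[w] & ~closed & v_high_mask
                extend(subg + (w,), m | new, closed | adj[w] | lsb, v_high_mask, cur)

    root = tree.root
    for v in range(n):
        v_high_mask = -1 << (v + 1)
        ext0 = adj[v] & v_high_mask
        # closed set = subgraph plus its whole neighbourhood
        extend((v,), ext0, adj[v] | (1 << v), v_high_mask, root)

    result.total = state["total"]
    result.excluded = state["excluded"]
    result.new_leaves = state["new_leaves"]
    result.canonical_calls = registry.canonical_calls - calls_before
    if collect_leaf_members:
        result.leaf_members = leaf_members
    if record_vertex_sets:
        result.vertex_sets = vertex_sets
    for cid, c in counts.items():
        rec = registry.record(cid)
        rec.counts[network] = rec.counts.get(network, 0) + c
    return result


def brute_force_census(g: Graph, k: int,
                       registry: Optional[ClassRegistry] = None) -> Census:
    """Oracle census: classify every connected k-subset directly.

    Enumerates all C(n, k) vertex subsets, keeps those inducing a
    weakly connected subgraph and labels each with
    :func:`canonical_label` (memoized per adjacency pattern, not per
    leaf — there is no tree here).  Intended for small n.
    """
    if k < 2 or k > g.n_vertices:
        raise GraphError(f"motif size k={k} outside 2..n={g.n_vertices}")
    if registry is None:
        registry = ClassRegistry()
    adj = g.adj_masks
    result = Census()
    label_cache: dict[tuple[int, ...], str] = {}

    for subset in combinations(range(g.n_vertices), k):
        # connectivity over the union (weak) adjacency
        members = 0
        for v in subset:
            members |= 1 << v
        seen = 1 << subset[0]
        frontier = seen
        while frontier:
            nxt = 0
            m = frontier
            while m:
                lsb = m & -m
                v = lsb.bit_length() - 1
                m ^= lsb
                nxt |= adj[v] & members & ~seen
            seen |= nxt
            frontier = nxt
        if seen != members:
            continue
        matrix = induced_adjacency(g, subset)
        key = tuple(int("".join(map(str, row)), 2) for row in matrix)
        label = label_cache.get(key)
        if label is None:
            label = canonical_label(matrix)
            registry.canonical_calls += 1
            label_cache[key] = label
        cid = registry.classify(label)
        result.total += 1
        if cid is None:
            result.excluded += 1
            continue
        result.counts[cid] = result.counts.get(cid, 0) + 1
    result.canonical_calls = registry.canonical_calls
    return result
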