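"""The quaternary prefix tree that memoizes isomorphism-class lookups.

Each enumerated k-subgraph traces a root-to-leaf path of length
``1 + 2 + ... + (k-1) = k(k-1)/2``: when the ESU recursion adds its
e-th vertex ``w``, the tree is descended one level per already-present
subgraph vertex ``u`` using the edge-pattern symbol between ``u`` and
``w`` (see :func:`motifquad.graph.edge_symbol`).  Two subgraphs that
reach the same leaf saw identical connection patterns in arrival order
and are therefore isomorphic, so the leaf can cache the class resolved
by the first arrival and spare every later one a canonical-labeling
call.  The converse does not hold: isomorphic subgraphs enumerated in
different vertex orders land on different leaves, and several leaves
may point to one class.

The tree structure keeps growing across the original network and the
whole random ensemble; only the class registry is frozen for random
networks.  A leaf whose pattern resolves, under a frozen registry, to a
class absent from the original network caches the sentinel
:data:`NOVEL_CLASS` so the (futile) canonical labeling also runs once.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .graph import Graph, SLOT_SYMBOL, SYMBOL_SLOT, edge_symbol
from .canonical import ClassRegistry, canonical_label, induced_adjacency


class QuatTreeError(RuntimeError):
    """Internal inconsistency in quaternary-tree bookkeeping."""


#: Sentinel cached on leaves whose class does not exist in a frozen registry.
NOVEL_CLASS = -1


class QuatNode:
    """Tree node with up to four children, one per edge symbol.

    ``children`` is a fixed 4-slot list indexed by
    :data:`motifquad.graph.SYMBOL_SLOT`; ``pointer`` is the memoized
    class id, meaningful only on leaves (depth ``k(k-1)/2``).
    """

    __slots__ = ("children", "pointer", "depth")

    def __init__(self, depth: int = 0) -> None:
        self.children: list[Optional["QuatNode"]] = [None, None, None, None]
        self.pointer: Optional[int] = None
        self.depth = depth


class QuatTree:
    """Rooted quaternary tree shared by all censuses of one run."""

    def __init__(self) -> None:
        self.root = QuatNode(depth=0)

    def n_nodes(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += 1
            stack.extend(c for c in node.children if c is not None)
        return count

    def n_resolved_leaves(self) -> int:
        """Leaves whose class pointer has been set (one canonical call each)."""
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.pointer is not None:
                count += 1
            stack.extend(c for c in node.children if c is not None)
        return count

    def dump(self) -> str:
        """Indented debug rendering: depth, slot symbol, cached class id."""
        lines: list[str] = ["root"]

        def walk(node: QuatNode, indent: int) -> None:
            for slot, child in enumerate(node.children):
                if child is None:
                    continue
                ptr = "" if child.pointer is None else f" -> class {child.pointer}"
                lines.append(f"{'  ' * indent}[{SLOT_SYMBOL[slot]:+d}] depth={child.depth}{ptr}")
                walk(child, indent + 1)

        walk(self.root, 1)
        return "\n".join(lines)


def search_step(tree: QuatTree, cur: QuatNode,
                subgraph_vertices: Sequence[int], w: int,
                g: Graph, grow: bool = True) -> Optional[QuatNode]:
    """Descend one level per subgraph vertex using the edge code to ``w``.

    ``cur`` must sit at depth ``e(e-1)/2`` for ``e`` current subgraph
    vertices (in ESU insertion order); the returned node lies
    ``len(subgraph_vertices)`` levels deeper.  With ``grow=True``
    missing children are created on the way; with ``grow=False`` a
    missing child means the pattern was never seen and ``None`` is
    returned.
    """
    e = len(subgraph_vertices)
    if cur.depth != e * (e - 1) // 2:
        raise QuatTreeError(
            f"node at depth {cur.depth}, expected {e * (e - 1) // 2} "
            f"for {e} subgraph vertices")
    node = cur
    for u in subgraph_vertices:
        slot = SYMBOL_SLOT[edge_symbol(g, u, w)]
        child = node.children[slot]
        if child is None:
            if not grow:
                return None
            child = QuatNode(depth=node.depth + 1)
            node.children[slot] = child
        node = child
    return node


def resolve_leaf(leaf: QuatNode, subgraph_vertices: Sequence[int],
                 g: Graph, registry: ClassRegistry) -> Optional[int]:
    """Resolve a full-depth leaf to its isomorphism-class id.

    A previously resolved leaf returns its cached pointer with no
    canonical-labeling work.  A fresh leaf triggers exactly one
    canonical labeling and a registry lookup; under a frozen registry an
    unknown label yields ``None`` (the subgraph is excluded from the
    census) and the leaf caches that verdict.
    """
    k = len(subgraph_vertices)
    if leaf.depth != k * (k - 1) // 2:
        raise QuatTreeError(
            f"leaf at depth {leaf.depth}, expected {k * (k - 1) // 2} for k={k}")
    if leaf.pointer is not None:
        return None if leaf.pointer == NOVEL_CLASS else leaf.pointer
    label = canonical_label(induced_adjacency(g, subgraph_vertices))
    registry.canonical_calls += 1
    class_id = registry.classify(label)
    leaf.pointer = NOVEL_CLASS if class_id is None else class_id
    return class_id
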