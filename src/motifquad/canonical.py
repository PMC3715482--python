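"""Canonical labeling of small induced subgraphs and the class registry.

A canonical label here is the minimum row-major adjacency bit-string of
a k-vertex graph over all vertex permutations: two graphs receive the
same label iff they are isomorphic, and the label is a fixed point (the
label of the canonical form is the label itself).  Exhaustive
minimisation over k! orderings is exact and entirely adequate at motif
scale because the enumerator memoizes labels on quaternary-tree leaves:
the labeling routine runs once per distinct leaf, not once per subgraph.

The registry keyed by canonical label plays the role a binary search
tree over label bits would: an exact label -> class lookup.  While a
registry is *frozen* (random-network census) its membership never
changes and unknown labels resolve to "absent".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

from .graph import Graph, GraphError

BitMatrix = Sequence[Sequence[int]]


def induced_adjacency(g: Graph, vertices: Sequence[int]) -> list[list[int]]:
    """k x k 0/1 adjacency of the subgraph induced by ``vertices``.

    Entry ``(i, j)`` is 1 iff the arc ``vertices[i] -> vertices[j]``
    exists; the diagonal is zero; symmetric for undirected graphs.
    """
    if len(set(vertices)) != len(vertices):
        raise GraphError("duplicate vertices in induced subgraph")
    k = len(vertices)
    return [[1 if i != j and g.has_arc(vertices[i], vertices[j]) else 0
             for j in range(k)] for i in range(k)]


def canonical_label(m: BitMatrix) -> str:
    """Minimum row-major adjacency bit-string over vertex permutations.

    Returns a string of ``k*k`` characters in ``{'0','1'}``.  Invariant
    under any relabeling of the input matrix, so equal labels certify
    isomorphism and vice versa.
    """
    k = len(m)
    rows = [tuple(row) for row in m]
    for i, row in enumerate(rows):
        if len(row) != k:
            raise GraphError("adjacency matrix must be square")
        if row[i]:
            raise GraphError("nonzero diagonal: self-loops are not supported")
    if k == 1:
        return "0"

    best: tuple[int, ...] | None = None
    for perm in permutations(range(k)):
        flat: list[int] = []
        worse = False
        better = best is None
        for i in perm:
            seg = tuple(rows[i][j] for j in perm)
            flat.extend(seg)
            if not better:
                n = len(flat)
                ref = best[n - k:n]  # type: ignore[index]
                if seg > ref:  # row-by-row early exit against the incumbent
                    worse = True
                    break
                if seg < ref:
                    better = True
        if better and not worse:
            best = tuple(flat)
    assert best is not None
    return "".join("1" if b else "0" for b in best)


@dataclass
class ClassRecord:
    """One isomorphism class: id, canonical label, per-network counters."""

    class_id: int
    canonical_label: str
    counts: dict = field(default_factory=dict)  # network tag -> occurrences


class ClassRegistry:
    """Canonical-label-keyed store of isomorphism classes.

    Unfrozen, :meth:`classify` creates a class for every new label;
    frozen, membership is immutable and unknown labels return ``None``.
    The count of :attr:`canonical_calls` is maintained by the census and
    reported in run summaries.
    """

    def __init__(self) -> None:
        self._by_label: dict[str, ClassRecord] = {}
        self._by_id: list[ClassRecord] = []
        self.frozen: bool = False
        self.canonical_calls: int = 0

    def __len__(self) -> int:
        return len(self._by_id)

    def classify(self, label: str) -> Optional[int]:
        """Resolve a canonical label to a class id.

        Unfrozen: existing or newly created id (new ids are assigned
        densely in discovery order).  Frozen: the existing id, or
        ``None`` for a label absent from the original network.
        """
        rec = self._by_label.get(label)
        if rec is not None:
            return rec.class_id
        if self.frozen:
            return None
        rec = ClassRecord(class_id=len(self._by_id), canonical_label=label)
        self._by_label[label] = rec
        self._by_id.append(rec)
        return rec.class_id

    def record(self, class_id: int) -> ClassRecord:
        return self._by_id[class_id]

    def records(self) -> list[ClassRecord]:
        return list(self._by_id)

    def freeze(self) -> None:
        self.frozen = True

    def export_lines(self, network: str = "original") -> list[str]:
        """One ``class_id canonical_label count`` line per class."""
        return [f"{r.class_id} {r.canonical_label} {r.counts.get(network, 0)}"
                for r in self._by_id]
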