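"""Show the leaf memoization that makes the census cheap.

Run: python examples/quaternary_tree_memoization.py
"""

from motifquad import (ClassRegistry, FixtureSpec, Graph, QuatTree, census,
                       generate)

# On K8 every vertex pair is mutually connected, so every enumerated
# subgraph descends the tree with the same symbol at every level: all 70
# subgraphs of size 4 share one leaf and canonical labeling runs once.
k8 = generate(FixtureSpec(kind="complete", n=8, directed=False))
reg = ClassRegistry()
c = census(k8, 4, registry=reg)
print(f"K8, k=4: {c.total} subgraphs, {len(c.counts)} class, "
      f"{reg.canonical_calls} canonical-labeling call(s)")

# A small directed graph, with the tree printed: each root-to-leaf path
# spells the arrival-order edge pattern of the subgraphs it classified.
g = Graph(4, [(0, 1), (1, 2), (2, 0), (2, 3)], directed=True)
tree, reg = QuatTree(), ClassRegistry()
c = census(g, 3, tree=tree, registry=reg)
print(f"\nsmall digraph, k=3: {c.total} subgraphs, {len(c.counts)} classes, "
      f"{reg.canonical_calls} canonical calls")
print(tree.dump())
# Symbols on the paths: -1 = arc old->new, 1 = arc new->old, 2 = mutual,
# 0 = no connection.  Leaves annotate the isomorphism class they cache.
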