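"""Independent oracles shared by the test modules.

These deliberately avoid the package's canonical-labeling and census
code paths: isomorphism is decided by brute-force permutation search or
by networkx, so agreement is evidence rather than tautology.
"""

from itertools import permutations

import networkx as nx


def perm_isomorphic(m1, m2) -> bool:
    """Brute-force isomorphism test on two 0/1 adjacency matrices."""
    k = len(m1)
    if len(m2) != k:
        return False
    rows1 = [tuple(r) for r in m1]
    for perm in permutations(range(k)):
        if all(rows1[i][j] == m2[pi][pj]
               for i, pi in enumerate(perm) for j, pj in enumerate(perm)):
            return True
    return False


def matrix_to_nx(m, directed: bool):
    g = nx.DiGraph() if directed else nx.Graph()
    k = len(m)
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(k):
            if m[i][j]:
                g.add_edge(i, j)
    return g


def nx_isomorphic(m1, m2, directed: bool) -> bool:
    return nx.is_isomorphic(matrix_to_nx(m1, directed), matrix_to_nx(m2, directed))


def graph_to_nx(g):
    h = nx.DiGraph() if g.directed else nx.Graph()
    h.add_nodes_from(range(g.n_vertices))
    h.add_edges_from(g.arcs())
    return h
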