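"""Canonical labeling and the class registry, checked against networkx."""

import random
from itertools import combinations, permutations

import pytest
from hypothesis import given, settings, strategies as st

from motifquad import (ClassRegistry, Graph, canonical_label,
                       induced_adjacency)
from motifquad.graph import GraphError

from oracles import nx_isomorphic


def permute(m, perm):
    k = len(m)
    return [[m[perm[i]][perm[j]] for j in range(k)] for i in range(k)]


def label_to_matrix(label):
    k = round(len(label) ** 0.5)
    return [[int(label[i * k + j]) for j in range(k)] for i in range(k)]


class TestInducedAdjacency:
    def setup_method(self):
        self.g = Graph(3, [(0, 1), (1, 2)], directed=True)  # path a->b->c

    def test_forward_order(self):
        assert induced_adjacency(self.g, [0, 1, 2]) == [
            [0, 1, 0], [0, 0, 1], [0, 0, 0]]

    def test_reversed_order_relabels(self):
        assert induced_adjacency(self.g, [2, 1, 0]) == [
            [0, 0, 0], [1, 0, 0], [0, 1, 0]]

    def test_undirected_edge_symmetric(self):
        g = Graph(2, [(0, 1)], directed=False)
        assert induced_adjacency(g, [0, 1]) == [[0, 1], [1, 0]]

    def test_duplicate_vertices_rejected(self):
        with pytest.raises(GraphError):
            induced_adjacency(self.g, [0, 0, 1])


class TestCanonicalLabel:
    def test_permutation_invariance_directed_path(self):
        m = [[0, 1, 0], [0, 0, 1], [0, 0, 0]]
        assert canonical_label(m) == canonical_label(permute(m, (2, 1, 0)))

    def test_cycle_and_path_distinct(self):
        path = [[0, 1, 0], [0, 0, 1], [0, 0, 0]]
        cycle = [[0, 1, 0], [0, 0, 1], [1, 0, 0]]
        assert canonical_label(path) != canonical_label(cycle)

    def test_label_is_fixed_point(self):
        m = [[0, 1, 1], [0, 0, 1], [1, 0, 0]]
        label = canonical_label(m)
        assert canonical_label(label_to_matrix(label)) == label

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(GraphError):
            canonical_label([[1]])

    def test_single_vertex(self):
        assert canonical_label([[0]]) == "0"

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_random_matrix_invariant_under_relabeling(self, seed):
        rng = random.Random(seed)
        k = rng.randint(2, 5)
        m = [[rng.random() < 0.4 and i != j and 1 or 0 for j in range(k)]
             for i in range(k)]
        perm = list(range(k))
        rng.shuffle(perm)
        assert canonical_label(m) == canonical_label(permute(m, perm))

    @pytest.mark.parametrize("k,directed", [(3, True), (4, True), (4, False)])
    def test_partitions_exactly_as_isomorphism(self, k, directed):
        """Equal labels iff isomorphic, exhaustively over all k-vertex graphs."""
        pairs = [(i, j) for i in range(k) for j in range(k)
                 if (i < j if not directed else i != j)]
        by_label = {}
        for bits in range(1 << len(pairs)):
            m = [[0] * k for _ in range(k)]
            for idx, (i, j) in enumerate(pairs):
                if (bits >> idx) & 1:
                    m[i][j] = 1
                    if not directed:
                        m[j][i] = 1
            by_label.setdefault(canonical_label(m), []).append(m)
        # members of one label class are isomorphic to their representative
        rng = random.Random(0)
        for label, members in by_label.items():
            rep = members[0]
            sample = members if len(members) <= 6 else rng.sample(members, 6)
            for m in sample:
                assert nx_isomorphic(rep, m, directed)
        # representatives of distinct labels are non-isomorphic
        reps = [members[0] for members in by_label.values()]
        for a, b in combinations(reps, 2):
            assert not nx_isomorphic(a, b, directed)

    def test_connected_undirected_4_vertex_classes_number_six(self):
        """There are exactly 6 connected undirected graphs on 4 vertices."""
        labels = set()
        pairs = list(combinations(range(4), 2))
        for bits in range(1 << 6):
            m = [[0] * 4 for _ in range(4)]
            for idx, (i, j) in enumerate(pairs):
                if (bits >> idx) & 1:
                    m[i][j] = m[j][i] = 1
            # connectivity via DFS
            seen = {0}
            stack = [0]
            while stack:
                v = stack.pop()
                for u in range(4):
                    if m[v][u] and u not in seen:
                        seen.add(u)
                        stack.append(u)
            if len(seen) == 4:
                labels.add(canonical_label(m))
        assert len(labels) == 6


class TestClassRegistry:
    def test_new_label_gets_next_dense_id(self):
        reg = ClassRegistry()
        assert reg.classify("0110") == 0
        assert reg.classify("0000") == 1
        assert reg.classify("0110") == 0

    def test_frozen_known_label_resolves(self):
        reg = ClassRegistry()
        reg.classify("0110")
        reg.freeze()
        assert reg.classify("0110") == 0

    def test_frozen_unknown_label_absent(self):
        reg = ClassRegistry()
        reg.classify("0110")
        reg.freeze()
        assert reg.classify("0000") is None
        assert len(reg) == 1

    def test_size_monotone_unfrozen_constant_frozen(self):
        reg = ClassRegistry()
        sizes = []
        for lab in ["00", "0110", "0000", "0110"]:
            reg.classify(lab)
            sizes.append(len(reg))
        assert sizes == sorted(sizes)
        reg.freeze()
        for lab in ["1001", "0100"]:
            reg.classify(lab)
        assert len(reg) == sizes[-1]

    def test_export_lines_format(self):
        reg = ClassRegistry()
        cid = reg.classify("0110")
        reg.record(cid).counts["original"] = 7
        assert reg.export_lines() == ["0 0110 7"]
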