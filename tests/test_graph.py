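"""Edge-list I/O, preprocessing, and the four-symbol edge code."""

import pytest
from hypothesis import given, settings, strategies as st

from motifquad import (Graph, GraphError, edge_symbol, load_edge_list,
                       remove_self_loops, write_edge_list)


def _load_text(tmp_path, text, directed=True):
    path = tmp_path / "edges.txt"
    path.write_text(text)
    return load_edge_list(path, directed=directed)


class TestLoadEdgeList:
    def test_ids_remapped_in_first_appearance_order(self, tmp_path):
        g = _load_text(tmp_path, "1 2\n2 3\n")
        assert g.n_vertices == 3
        assert sorted(g.arcs()) == [(0, 1), (1, 2)]

    def test_duplicate_lines_collapsed(self, tmp_path):
        g = _load_text(tmp_path, "1 2\n1 2\n")
        assert g.n_arcs == 1

    def test_undirected_stored_symmetrically(self, tmp_path):
        g = _load_text(tmp_path, "5 7\n7 5\n", directed=False)
        assert g.n_vertices == 2
        assert sorted(g.arcs()) == [(0, 1), (1, 0)]
        assert g.n_edges == 1

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        g = _load_text(tmp_path, "# header\n% other\n\n4 9\n")
        assert g.n_vertices == 2 and g.n_arcs == 1

    def test_third_column_ignored(self, tmp_path):
        g = _load_text(tmp_path, "1 2 0.5\n")
        assert g.n_arcs == 1

    def test_self_loops_dropped_silently(self, tmp_path):
        g = _load_text(tmp_path, "3 3\n3 4\n")
        assert g.n_vertices == 2
        assert sorted(g.arcs()) == [(0, 1)]

    def test_malformed_line_names_line_number(self, tmp_path):
        with pytest.raises(GraphError, match=":2:"):
            _load_text(tmp_path, "1 2\nbogus\n")

    def test_empty_file_is_an_error(self, tmp_path):
        with pytest.raises(GraphError, match="empty"):
            _load_text(tmp_path, "# nothing\n")


class TestRemoveSelfLoops:
    def _with_loop(self, arcs_with_loops, n, directed=True):
        g = Graph(n, directed=directed)
        for u, w in arcs_with_loops:
            g.out_adj[u].add(w)
            g.in_adj[w].add(u)
        return g

    def test_loops_deleted_vertices_kept(self):
        g = self._with_loop([(0, 0), (0, 1)], n=2)
        out = remove_self_loops(g)
        assert sorted(out.arcs()) == [(0, 1)]
        assert out.n_vertices == 2

    def test_idempotent_on_loop_free_graph(self):
        g = Graph(3, [(0, 1), (1, 2)])
        assert remove_self_loops(g) == g

    def test_only_loops_leaves_empty_arc_set(self):
        g = self._with_loop([(0, 0)], n=1)
        out = remove_self_loops(g)
        assert out.n_arcs == 0 and out.n_vertices == 1


class TestEdgeSymbol:
    @pytest.mark.parametrize("arcs,expected", [
        ([(0, 1), (1, 0)], 2),   # mutual
        ([], 0),                 # none
        ([(0, 1)], -1),          # only u -> w
        ([(1, 0)], 1),           # only w -> u
    ])
    def test_directed_symbols(self, arcs, expected):
        g = Graph(2, arcs, directed=True)
        assert edge_symbol(g, 0, 1) == expected

    def test_same_vertex_is_domain_error(self):
        g = Graph(2, [(0, 1)])
        with pytest.raises(GraphError):
            edge_symbol(g, 1, 1)

    def test_undirected_symbols_only_0_or_2(self):
        g = Graph(3, [(0, 1)], directed=False)
        symbols = {edge_symbol(g, u, w)
                   for u in range(3) for w in range(3) if u != w}
        assert symbols <= {0, 2}


class TestInvariants:
    def test_degree_sums_equal_arc_count(self):
        g = Graph(5, [(0, 1), (1, 2), (2, 0), (3, 4)], directed=True)
        assert sum(len(s) for s in g.out_adj) == g.n_arcs
        assert sum(len(s) for s in g.in_adj) == g.n_arcs

    @given(st.integers(0, 10 ** 6), st.booleans())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_write_load_round_trip_is_stable(self, seed, directed):
        """Writing then reloading reaches a fixed point with the same arcs."""
        import random
        import tempfile
        rng = random.Random(seed)
        n = rng.randint(2, 12)
        arcs = {(u, w) for u in range(n) for w in range(n)
                if u != w and rng.random() < 0.3}
        if directed:
            g = Graph(n, arcs, directed=True)
        else:
            g = Graph(n, {(min(u, w), max(u, w)) for u, w in arcs}, directed=False)
        if g.n_arcs == 0:
            return
        with tempfile.TemporaryDirectory() as tmp_str:
            from pathlib import Path
            tmp = Path(tmp_str)
            write_edge_list(g, tmp / "a.txt")
            h = load_edge_list(tmp / "a.txt", directed=directed)
            write_edge_list(h, tmp / "b.txt")
            h2 = load_edge_list(tmp / "b.txt", directed=directed)
            written = [tuple(map(int, line.split()))
                       for line in (tmp / "b.txt").read_text().split("\n") if line]
        # replay the loader's first-appearance remapping and compare arc sets
        remap = {}
        for u, w in written:
            for raw in (u, w):
                remap.setdefault(raw, len(remap))
        expected = {(remap[u], remap[w]) for u, w in written}
        if not directed:
            expected |= {(w, u) for u, w in expected}
        assert set(h2.arcs()) == expected
        assert h2.n_edges == h.n_edges == g.n_edges
        # isolated vertices are not representable in an edge list
        non_isolated = sum(1 for v in range(n)
                           if g.out_adj[v] or g.in_adj[v])
        assert h.n_vertices == non_isolated
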