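"""Natural visibility graph: hand examples, analytic families, oracle equivalence."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import boldvis as bv
from conftest import random_series
from oracles import brute_visibility_edges


def edges(g: nx.Graph) -> set[tuple[int, int]]:
    return {tuple(sorted(e)) for e in g.edges()}


class TestHandExamples:
    def test_three_point_valley_forms_triangle(self):
        # chord 0-2 passes at height 2.5 over t=1, above y_1 = 1
        g = bv.visibility_graph(bv.TimeSeries(np.array([3.0, 1.0, 2.0])))
        assert edges(g) == {(0, 1), (1, 2), (0, 2)}

    def test_strictly_convex_series_is_complete(self):
        ts = bv.TimeSeries(np.array([float(i * i) for i in range(5)]))
        g = bv.visibility_graph(ts)
        assert edges(g) == edges(nx.complete_graph(5))

    def test_strictly_concave_series_is_path(self):
        ts = bv.TimeSeries(np.array([-float((i - 2) ** 2) for i in range(5)]))
        g = bv.visibility_graph(ts)
        assert edges(g) == {(i, i + 1) for i in range(4)}

    def test_collinear_semantics(self):
        ramp = bv.TimeSeries(np.array([2.0 * i for i in range(5)]))
        blocking = bv.visibility_graph(ramp, collinear_blocks=True)
        assert edges(blocking) == {(i, i + 1) for i in range(4)}
        admissible = bv.visibility_graph(ramp, collinear_blocks=False)
        assert edges(admissible) == edges(nx.complete_graph(5))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bv.visibility_graph(bv.TimeSeries(np.array([1.0])))


class TestOracleEquivalence:
    @pytest.mark.parametrize("n", [10, 25, 50])
    def test_matches_brute_force_on_random_series(self, n):
        for seed in range(40):
            ts = random_series(seed * 3 + n, n)
            got = edges(bv.visibility_graph(ts))
            want = brute_visibility_edges(ts.times, ts.values)
            assert got == want, f"seed={seed}, n={n}"

    def test_matches_brute_force_with_collinear_admissible(self):
        # integer-valued series manufacture exact collinear triples
        for seed in range(25):
            rng = np.random.default_rng(seed)
            ts = bv.TimeSeries(rng.integers(0, 4, size=15).astype(float))
            for flag in (True, False):
                got = edges(bv.visibility_graph(ts, collinear_blocks=flag))
                want = brute_visibility_edges(ts.times, ts.values, collinear_blocks=flag)
                assert got == want, f"seed={seed}, collinear_blocks={flag}"

    def test_matches_networkx_reference(self):
        # independent published implementation of the same construction
        for seed in range(20):
            ts = random_series(1000 + seed, 30)
            got = edges(bv.visibility_graph(ts))
            want = edges(nx.visibility_graph(ts.values))
            assert got == want


class TestInvariants:
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_contains_hamiltonian_path_and_is_connected(self, seed, n):
        g = bv.visibility_graph(random_series(seed, n))
        assert all(g.has_edge(i, i + 1) for i in range(n - 1))
        assert nx.is_connected(g)
        assert n - 1 <= g.number_of_edges() <= n * (n - 1) // 2

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=-100.0, max_value=100.0),
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=-100.0, max_value=100.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_affine_invariance(self, seed, a, b, c, d):
        ts = random_series(seed, 25)
        base = edges(bv.visibility_graph(ts))
        mapped = bv.TimeSeries(a * ts.values + b, c * ts.times + d)
        assert edges(bv.visibility_graph(mapped)) == base

    def test_edge_count_bounds_are_attained(self):
        n = 12
        convex = bv.TimeSeries(np.array([float(i * i) for i in range(n)]))
        concave = bv.TimeSeries(np.array([-float(i * i) for i in range(n)]))
        assert bv.visibility_graph(convex).number_of_edges() == n * (n - 1) // 2
        assert bv.visibility_graph(concave).number_of_edges() == n - 1


class TestGraphIO:
    def test_edgelist_round_trip(self, tmp_path):
        g = bv.visibility_graph(random_series(5, 40))
        path = tmp_path / "graph.edges"
        bv.write_edgelist(g, path)
        back = bv.read_edgelist(path)
        assert set(back.nodes()) == set(g.nodes())
        assert edges(back) == edges(g)

    def test_edgelist_preserves_isolated_nodes(self, tmp_path):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        g.add_edge(0, 1)
        path = tmp_path / "graph.edges"
        bv.write_edgelist(g, path)
        assert set(bv.read_edgelist(path).nodes()) == set(range(5))

    def test_graphml_round_trip(self, tmp_path):
        g = bv.visibility_graph(random_series(6, 30))
        path = tmp_path / "graph.graphml"
        bv.write_graphml(g, path)
        back = bv.read_graphml(path)
        assert edges(back) == edges(g)
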