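"""Centralities vs brute-force BFS oracles; median screening semantics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herbnet import (
    InputError,
    ValidationError,
    centrality_table,
    compute_betweenness,
    compute_closeness,
    compute_degree,
    iterative_screen,
    median_thresholds,
    screen_round,
)

from ._oracles import brute_betweenness, brute_closeness
from .conftest import random_graph


class TestCentralities:
    def test_star_degrees(self):
        g = nx.star_graph(3)
        deg = compute_degree(g)
        assert deg[0] == 3 and all(deg[i] == 1 for i in range(1, 4))

    def test_edgeless_graph_all_zero(self):
        g = nx.empty_graph(5)
        assert set(compute_degree(g).values()) == {0}
        assert set(compute_betweenness(g).values()) == {0}
        assert set(compute_closeness(g).values()) == {0}

    def test_path3_analytic_values(self):
        g = nx.path_graph(["a", "b", "c"])
        bet = compute_betweenness(g)
        assert bet["b"] == pytest.approx(1.0)
        assert bet["a"] == bet["c"] == 0.0
        clo = compute_closeness(g)
        assert clo["b"] == pytest.approx(1.0)
        assert clo["a"] == pytest.approx(2 / 3)

    def test_complete_graph_betweenness_zero(self):
        assert set(compute_betweenness(nx.complete_graph(4)).values()) == {0.0}

    def test_star5_closeness(self):
        g = nx.star_graph(4)  # center 0 plus 4 leaves
        clo = compute_closeness(g)
        assert clo[0] == pytest.approx(1.0)
        assert clo[1] == pytest.approx(4 / 7)

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("z")
        assert compute_closeness(g)["z"] == 0.0

    def test_degree_sum_is_twice_edges(self):
        g = random_graph(99, n=30, p=0.2)
        assert sum(compute_degree(g).values()) == 2 * g.number_of_edges()

    @pytest.mark.parametrize("seed", range(12))
    def test_match_bfs_enumeration_oracle(self, seed):
        g = random_graph(seed, n=4 + 2 * seed, p=0.25)
        bet = compute_betweenness(g)
        clo = compute_closeness(g)
        bet_ref = brute_betweenness(g)
        clo_ref = brute_closeness(g)
        for v in g.nodes():
            assert bet[v] == pytest.approx(bet_ref[v], abs=1e-9)
            assert clo[v] == pytest.approx(clo_ref[v], abs=1e-9)

    def test_self_loop_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "a")
        with pytest.raises(ValidationError, match="self-loop"):
            compute_degree(g)


class TestMedians:
    def test_odd_and_even_count(self):
        ct = pd.DataFrame(
            {"node": list("abcde"), "degree": [1, 2, 2, 2, 1],
             "betweenness": [0.0] * 5, "closeness": [0.0] * 5}
        )
        assert median_thresholds(ct)[0] == 2
        ct2 = ct.iloc[:2]
        assert median_thresholds(ct2)[0] == 1.5

    def test_empty_table_rejected(self):
        with pytest.raises(InputError):
            median_thresholds(pd.DataFrame(columns=["degree", "betweenness", "closeness"]))

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=25))
    def test_matches_sort_based_reference(self, values):
        ct = pd.DataFrame(
            {"node": range(len(values)), "degree": values,
             "betweenness": values, "closeness": values}
        )
        s = sorted(values)
        n = len(s)
        ref = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert median_thresholds(ct)[0] == pytest.approx(ref)


class TestScreening:
    def test_path5_worked_example(self, path5):
        rnd, induced = screen_round(path5)
        m_d, m_b, m_c = rnd.thresholds
        assert m_d == 2
        assert m_b == pytest.approx(0.5)
        assert m_c == pytest.approx(4 / 7)
        assert rnd.survivors == {"b", "c", "d"}
        assert rnd.induced_edge_count == 2
        assert set(induced.edges()) == {("b", "c"), ("c", "d")}

    def test_path5_second_round_converges(self, path5):
        result = iterative_screen(path5, rounds=2)
        assert [len(r.survivors) for r in result.rounds] == [3, 3]
        assert result.rounds[1].thresholds == pytest.approx((1.0, 0.0, 2 / 3))
        assert result.final_hubs == {"b", "c", "d"}
        assert result.converged

    def test_complete_graph_all_survive(self):
        rnd, _ = screen_round(nx.complete_graph(5))
        assert len(rnd.survivors) == 5

    def test_edgeless_graph_converges_immediately(self):
        result = iterative_screen(nx.empty_graph(6), rounds=2, until_stable=True)
        assert result.converged
        assert len(result.final_hubs) == 6
        assert len(result.rounds) == 1

    def test_strict_mode_eliminates_ties(self):
        # strict (>) comparison on a vertex-transitive graph removes everyone
        result = iterative_screen(nx.cycle_graph(6), rounds=1, inclusive=False)
        assert result.final_hubs == set()
        assert not result.converged

    def test_monotone_shrinkage_and_threshold_soundness(self):
        g = random_graph(5, n=40, p=0.15)
        result = iterative_screen(g, rounds=3)
        sizes = [r.n_nodes_in for r in result.rounds] + [len(result.rounds[-1].survivors)]
        assert sizes == sorted(sizes, reverse=True)
        current = g
        for rnd in result.rounds:
            ct = centrality_table(current)
            m_d, m_b, m_c = rnd.thresholds
            for _, row in ct.iterrows():
                meets = (
                    row.degree >= m_d and row.betweenness >= m_b and row.closeness >= m_c
                )
                assert meets == (row.node in rnd.survivors)
            current = current.subgraph(rnd.survivors).copy()

    def test_permutation_invariance(self):
        g = random_graph(11, n=25, p=0.2)
        mapping = {v: f"relabel_{v}" for v in g.nodes()}
        h = nx.relabel_nodes(g, mapping)
        res_g = iterative_screen(g, rounds=2)
        res_h = iterative_screen(h, rounds=2)
        assert {mapping[v] for v in res_g.final_hubs} == res_h.final_hubs
        for a, b in zip(res_g.rounds, res_h.rounds):
            assert a.thresholds == pytest.approx(b.thresholds)
            assert a.induced_edge_count == b.induced_edge_count

    def test_planted_hub_recovery(self, dataset):
        result = iterative_screen(dataset.ppi, rounds=2)
        truth = dataset.truth.planted_hub_ids
        tp = result.final_hubs & truth
        assert len(tp) / len(truth) >= 0.8
        assert len(tp) / len(result.final_hubs) >= 0.6
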