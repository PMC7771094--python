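"""Dense module search: examples, invariants, and a brute-force oracle.

The oracle re-implements the growth rule naively — recomputing the mean
edge weight for every candidate at every step — independently of the
heap-based implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_coppi, random_coppi
from coppinet.module_search import (
    expand_module,
    module_score,
    search_modules,
    seed_edges,
)


# --- independent oracle -------------------------------------------------

def brute_force_expand(graph, seed_u, seed_v):
    nodes = {seed_u, seed_v}
    edges = {frozenset((seed_u, seed_v)): graph[seed_u][seed_v]["weight"]}
    while True:
        total, m = sum(edges.values()), len(edges)
        candidates = []
        for u, v, d in graph.edges(data=True):
            if frozenset((u, v)) in edges:
                continue
            if u in nodes or v in nodes:
                a, b = sorted((u, v))
                candidates.append((a, b, d["weight"]))
        if not candidates:
            break
        best = min(
            candidates,
            key=lambda e: (-(total + e[2]) / (m + 1), -e[2], e[0], e[1]),
        )
        if (total + best[2]) / (m + 1) <= total / m:
            break
        edges[frozenset((best[0], best[1]))] = best[2]
        nodes.update(best[:2])
    return nodes, sum(edges.values()) / len(edges), edges


def brute_force_search(graph, min_weight=0.5, min_nodes=4):
    results = {}
    for u, v, d in graph.edges(data=True):
        if d["weight"] < min_weight:
            continue
        nodes, em, edges = brute_force_expand(graph, u, v)
        if len(nodes) < min_nodes:
            continue
        key = frozenset(nodes)
        if key not in results or em > results[key][0]:
            results[key] = (em, edges)
    return {
        key: (em, {tuple(sorted(k)) for k in edges})
        for key, (em, edges) in results.items()
    }


# --- unit examples ------------------------------------------------------

class TestModuleScore:
    def test_mean_of_weights(self):
        assert module_score([0.6, 0.8, 0.7]) == pytest.approx(0.7)

    def test_single_edge(self):
        assert module_score([0.55]) == pytest.approx(0.55)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            module_score([])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
           st.floats(0.01, 1.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_constant_weights_score_themselves(self, weights, w):
        assert module_score([w] * len(weights)) == pytest.approx(w)


class TestSeedEdges:
    def test_threshold_boundary_inclusive(self):
        coppi = make_coppi({("a", "b"): 0.49, ("b", "c"): 0.50, ("c", "d"): 0.51})
        weights = [w for _, _, w in seed_edges(coppi)]
        assert weights == [0.51, 0.50]

    def test_empty_network_gives_no_seeds(self):
        assert seed_edges(make_coppi({})) == []

    def test_equal_weights_sorted_lexicographically(self):
        coppi = make_coppi({("b", "c"): 0.7, ("a", "d"): 0.7, ("a", "b"): 0.7})
        assert [(u, v) for u, v, _ in seed_edges(coppi)] == [
            ("a", "b"), ("a", "d"), ("b", "c")
        ]


class TestExpandModule:
    def test_one_step_growth(self):
        coppi = make_coppi({("A", "B"): 0.9, ("B", "C"): 0.95})
        mod = expand_module(coppi, ("A", "B"))
        assert mod.nodes == frozenset("ABC")
        assert mod.em == pytest.approx(0.925)

    def test_isolated_seed_stays_alone(self):
        coppi = make_coppi({("A", "B"): 0.8, ("C", "D"): 0.6})
        mod = expand_module(coppi, ("A", "B"))
        assert mod.nodes == frozenset("AB")
        assert mod.em == pytest.approx(0.8)

    def test_worsening_candidate_rejected(self):
        # adding B-C would drop Em from 0.9 to 0.75
        coppi = make_coppi({("A", "B"): 0.9, ("B", "C"): 0.6})
        mod = expand_module(coppi, ("A", "B"))
        assert mod.nodes == frozenset("AB")
        assert mod.em == pytest.approx(0.9)

    def test_missing_seed_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            expand_module(make_coppi({("A", "B"): 0.9}), ("A", "C"))

    def test_final_score_at_least_seed_weight(self, rng):
        coppi = random_coppi(15, 0.3, rng)
        for u, v, w in seed_edges(coppi, 0.3)[:10]:
            assert expand_module(coppi, (u, v)).em >= w - 1e-12


class TestSearchModules:
    def test_all_weights_below_threshold_gives_nothing(self):
        coppi = make_coppi({("a", "b"): 0.3, ("b", "c"): 0.45})
        assert search_modules(coppi) == []

    def test_converging_seeds_deduplicated_keeping_higher_em(self):
        # seeds a-b and b-c both reach {a,b,c,d}; the b-c growth scores
        # higher ((0.92+0.94+0.96)/3) and is the one kept
        coppi = make_coppi({
            ("a", "b"): 0.90, ("b", "c"): 0.92, ("c", "d"): 0.94, ("a", "d"): 0.96,
        })
        mods = search_modules(coppi)
        assert len(mods) == 1
        assert mods[0].nodes == frozenset("abcd")
        assert mods[0].em == pytest.approx((0.92 + 0.94 + 0.96) / 3)

    def test_equal_weight_ties_do_not_extend(self):
        # strict improvement: a candidate equal to the current Em is refused
        coppi = make_coppi({("a", "b"): 0.9, ("b", "c"): 0.9})
        mod = expand_module(coppi, ("a", "b"))
        assert mod.nodes == frozenset("ab")

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        coppi = random_coppi(rng.integers(5, 11), 0.5, rng)
        ours = {
            m.nodes: (m.em, {(u, v) for u, v, _ in m.edges})
            for m in search_modules(coppi, min_weight=0.5, min_nodes=2)
        }
        oracle = brute_force_search(coppi.graph, min_weight=0.5, min_nodes=2)
        assert set(ours) == set(oracle)
        for key in oracle:
            assert ours[key][0] == pytest.approx(oracle[key][0])
            assert ours[key][1] == oracle[key][1]

    def test_local_optimality_and_score_floor(self, rng):
        coppi = random_coppi(60, 0.12, rng)
        mods = search_modules(coppi, min_weight=0.5, min_nodes=2)
        assert mods, "fixture should produce modules"
        for m in mods:
            assert m.em >= 0.5
            assert min(w for _, _, w in m.edges) >= 0.5
            # no single candidate addition improves Em
            in_module = {frozenset((u, v)) for u, v, _ in m.edges}
            for u, v, d in coppi.graph.edges(data=True):
                if frozenset((u, v)) in in_module:
                    continue
                if u in m.nodes or v in m.nodes:
                    grown = (m.em * m.n_edges + d["weight"]) / (m.n_edges + 1)
                    assert grown <= m.em + 1e-12

    def test_deterministic_output(self, rng):
        coppi = random_coppi(40, 0.15, rng)
        runs = [search_modules(coppi) for _ in range(2)]
        assert runs[0] == runs[1]

    def test_module_edges_form_connected_subgraph(self, rng):
        import networkx as nx

        coppi = random_coppi(30, 0.2, rng)
        for m in search_modules(coppi, min_nodes=2):
            sub = nx.Graph()
            sub.add_weighted_edges_from(m.edges)
            assert set(sub.nodes) == set(m.nodes)
            assert nx.is_connected(sub)
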