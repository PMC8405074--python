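"""MI estimation, permutation threshold, DPI pruning, module extraction."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netmark.coexpr import (
    CoexprConfig,
    apply_dpi,
    auto_bins,
    infer_network,
    mi_threshold,
    mutual_information,
    seed_module,
)
from netmark.synth import SynthConfig, make_coexpr_data


def mi_bruteforce(x, y, n_bins):
    """Direct summation of p log(p / (px py)) over the contingency cells,
    with the same equal-frequency rank binning."""
    def bins(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=int)
        ranks[order] = np.arange(len(v))
        return (ranks * n_bins) // len(v)

    bx, by = bins(np.asarray(x, float)), bins(np.asarray(y, float))
    n = len(bx)
    total = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            p = np.sum((bx == i) & (by == j)) / n
            if p > 0:
                px = np.sum(bx == i) / n
                py = np.sum(by == j) / n
                total += p * np.log(p / (px * py))
    return total


class TestMutualInformation:
    @pytest.mark.parametrize("n,b", [(100, 10), (96, 8), (120, 6)])
    def test_bijection_gives_log_b(self, rng, n, b):
        x = rng.normal(size=n)
        assert mutual_information(x, x, b) == pytest.approx(np.log(b), abs=1e-9)
        # any strictly monotone transform of x is still a bijection
        assert mutual_information(x, np.exp(x), b) == pytest.approx(
            np.log(b), abs=1e-9
        )

    def test_independent_vectors_near_zero(self, rng):
        x, y = rng.normal(size=10000), rng.normal(size=10000)
        assert mutual_information(x, y) < 0.02

    def test_matches_direct_summation(self, rng):
        for _ in range(20):
            n = int(rng.integers(16, 60))
            b = int(rng.integers(2, 6))
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert mutual_information(x, y, b) == pytest.approx(
                mi_bruteforce(x, y, b), abs=1e-12
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(8, 64), st.integers(2, 8))
    def test_symmetric_and_nonnegative(self, seed, n, b):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=n), r.normal(size=n)
        mi_xy = mutual_information(x, y, b)
        assert mi_xy == mutual_information(y, x, b)
        assert mi_xy >= 0.0

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="length"):
            mutual_information([1] * 10, [1] * 9)
        with pytest.raises(ValueError, match="constant"):
            mutual_information(np.ones(10), rng.normal(size=10))
        with pytest.raises(ValueError, match="at least 8"):
            mutual_information([1, 2, 3], [1, 2, 3])


class TestThreshold:
    def test_deterministic_under_seed(self, make_matrix, rng):
        m = make_matrix(rng.normal(size=(10, 50)))
        cfg = CoexprConfig()
        assert mi_threshold(m, cfg, seed=5) == mi_threshold(m, cfg, seed=5)

    def test_monotone_non_increasing_in_n(self, rng, make_matrix):
        thresholds = []
        for n in [32, 128, 512]:
            m = make_matrix(rng.normal(size=(10, n)))
            thresholds.append(mi_threshold(m, CoexprConfig(n_bins=4), seed=1))
        assert thresholds[0] >= thresholds[1] >= thresholds[2]

    def test_too_few_samples_rejected(self, make_matrix):
        m = make_matrix(np.arange(12.0).reshape(2, 6) + np.eye(2, 6))
        with pytest.raises(ValueError, match="at least 8"):
            mi_threshold(m, CoexprConfig())


def dpi_bruteforce(graph, epsilon):
    """Triangle scan by exhaustive node-triple enumeration."""
    removed = set()
    for a, b, c in itertools.combinations(graph.nodes(), 3):
        if not (graph.has_edge(a, b) and graph.has_edge(b, c) and graph.has_edge(a, c)):
            continue
        w = {
            frozenset((a, b)): graph.edges[a, b]["mi"],
            frozenset((b, c)): graph.edges[b, c]["mi"],
            frozenset((a, c)): graph.edges[a, c]["mi"],
        }
        for e, we in w.items():
            others = [v for k, v in w.items() if k != e]
            if we < min(others) * (1 - epsilon):
                removed.add(e)
    return removed


class TestDpi:
    def test_weakest_triangle_edge_removed(self):
        g = nx.Graph()
        g.add_edge("A", "B", mi=0.5)
        g.add_edge("B", "C", mi=0.4)
        g.add_edge("A", "C", mi=0.1)
        pruned, removed = apply_dpi(g, 0.0)
        assert removed == {frozenset(("A", "C"))}
        assert pruned.has_edge("A", "B") and pruned.has_edge("B", "C")

    def test_epsilon_one_disables_pruning(self, rng):
        g = nx.complete_graph(5)
        for a, b in g.edges():
            g.edges[a, b]["mi"] = float(rng.uniform(0.1, 1.0))
        pruned, removed = apply_dpi(g, 1.0)
        assert removed == set() and pruned.number_of_edges() == 10

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            g = nx.gnp_random_graph(n, 0.7, seed=int(rng.integers(2**31)))
            for a, b in g.edges():
                g.edges[a, b]["mi"] = float(rng.uniform(0.01, 1.0))
            eps = float(rng.uniform(0, 0.3))
            _, removed = apply_dpi(g, eps)
            assert removed == dpi_bruteforce(g, eps)

    def test_order_invariance(self, rng):
        g = nx.complete_graph(6)
        for a, b in g.edges():
            g.edges[a, b]["mi"] = float(rng.uniform(0.01, 1.0))
        h = nx.Graph()
        for a, b in reversed(list(g.edges())):
            h.add_edge(a, b, mi=g.edges[a, b]["mi"])
        assert apply_dpi(g, 0.1)[1] == apply_dpi(h, 0.1)[1]

    def test_bad_epsilon(self):
        with pytest.raises(ValueError):
            apply_dpi(nx.Graph(), 1.5)


class TestInferAndModule:
    def test_independent_genes_yield_no_edges(self, make_matrix, rng):
        m = make_matrix(rng.normal(size=(12, 200)))
        net, _ = infer_network(m, CoexprConfig(), seed=3)
        # 66 pairs at alpha=0.05: Binomial(66, 0.05), mean 3.3, sd 1.8
        assert net.number_of_edges() <= 9

    def test_module_connected_to_seed_before_and_after_dpi(self):
        cfg = SynthConfig(n_genes=20, module_size=6, module_loading=0.9, seed=31)
        m, truth = make_coexpr_data(cfg, "G0001", n_samples=300)
        net, audit = infer_network(m, CoexprConfig(), seed=31)
        passed = {
            frozenset((r.gene_a, r.gene_b)) for r in audit if r.passed_threshold
        }
        for g in truth.module_genes - {"G0001"}:
            assert frozenset(("G0001", g)) in passed
        module = seed_module(net, "G0001")
        assert len(module & truth.module_genes) >= 5

    def test_audit_invariant_removed_implies_passed(self):
        cfg = SynthConfig(n_genes=15, module_size=5, seed=32)
        m, _ = make_coexpr_data(cfg, "G0001", n_samples=200)
        _, audit = infer_network(m, CoexprConfig(), seed=32)
        assert all(r.passed_threshold for r in audit if r.removed_by_dpi)

    def test_pipeline_deterministic(self):
        cfg = SynthConfig(n_genes=10, module_size=4, seed=33)
        m, _ = make_coexpr_data(cfg, "G0001", n_samples=100)
        a, _ = infer_network(m, CoexprConfig(), seed=9)
        b, _ = infer_network(m, CoexprConfig(), seed=9)
        assert set(map(frozenset, a.edges())) == set(map(frozenset, b.edges()))

    def test_seed_module_star_and_isolated(self):
        star = nx.star_graph(4)
        assert seed_module(star, 0) == {0, 1, 2, 3, 4}
        g = nx.Graph()
        g.add_node("LONE")
        assert seed_module(g, "LONE") == {"LONE"}
        with pytest.raises(ValueError, match="MISSING"):
            seed_module(g, "MISSING")

    def test_auto_bins_sturges(self):
        assert auto_bins(8) == 4 and auto_bins(100) == 7 and auto_bins(1024) == 11
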