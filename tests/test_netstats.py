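import math

import networkx as nx
import numpy as np
import pytest

from polyvalent._errors import (
    ConvergenceError,
    DegenerateError,
    SizeError,
    UsageError,
)
from polyvalent.networks import DomainNetwork
from polyvalent.netstats import (
    betweenness,
    degree_sequence,
    fit_exponential_decay,
    fit_power_law,
    hits_scores,
    largest_biconnected,
    maximal_cliques,
    merge_largest_cliques,
    sample_discrete_power_law,
)
from oracles import (
    brute_force_betweenness,
    brute_force_biconnected_sets,
    brute_force_maximal_cliques,
    grid_search_alpha,
)


def undirected(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return DomainNetwork(g, directed=False)


def directed(edges, nodes=()):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return DomainNetwork(g, directed=True)


class TestDegrees:
    def test_triangle_and_star(self):
        assert degree_sequence(undirected([("A", "B"), ("B", "C"), ("A", "C")])) == [2, 2, 2]
        assert degree_sequence(undirected([("H", "A"), ("H", "B"), ("H", "C")])) == [3, 1, 1, 1]

    def test_directed_modes(self):
        net = directed([("a", "b"), ("a", "c")])
        assert degree_sequence(net, "out") == [2, 0, 0]
        assert degree_sequence(net, "in") == [1, 1, 0]
        assert degree_sequence(net, "total") == [2, 1, 1]

    def test_in_out_require_direction(self):
        with pytest.raises(UsageError):
            degree_sequence(undirected([("A", "B")]), "in")


class TestPowerLaw:
    def test_recovers_alpha_within_tolerance_of_grid_oracle(self):
        rng = np.random.default_rng(5)
        sample = sample_discrete_power_law(1000, alpha=2.5, xmin=1, rng=rng)
        fit = fit_power_law(sample, n_bootstrap=0)
        oracle = grid_search_alpha(sample, xmin=fit.xmin)
        assert abs(fit.alpha - oracle) <= 0.02
        assert abs(fit.alpha - 2.5) <= 0.2

    def test_geometric_sample_fits_worse_than_power_law_sample(self):
        rng = np.random.default_rng(7)
        pl = sample_discrete_power_law(1000, alpha=2.5, xmin=1, rng=rng)
        geo = rng.geometric(0.2, size=1000)
        assert fit_power_law(geo, 0).ks_stat > fit_power_law(pl, 0).ks_stat

    def test_too_few_or_degenerate(self):
        with pytest.raises(SizeError):
            fit_power_law([3] * 5, 0)
        with pytest.raises(DegenerateError):
            fit_power_law([3] * 50, 0)

    def test_bootstrap_p_well_calibrated_on_own_model(self):
        # data simulated from the fitted model should rarely be rejected
        rng = np.random.default_rng(13)
        high_p = 0
        n_rep = 30
        for _ in range(n_rep):
            sample = sample_discrete_power_law(300, alpha=2.3, xmin=2, rng=rng)
            fit = fit_power_law(sample, n_bootstrap=60, seed=int(rng.integers(2**31)))
            if fit.p_value > 0.05:
                high_p += 1
        assert high_p >= 0.8 * n_rep

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        sample = sample_discrete_power_law(200, 2.2, 1, rng)
        a = fit_power_law(sample, n_bootstrap=50, seed=9)
        b = fit_power_law(sample, n_bootstrap=50, seed=9)
        assert (a.alpha, a.xmin, a.ks_stat, a.p_value) == (b.alpha, b.xmin, b.ks_stat, b.p_value)


class TestExponentialFit:
    def test_exact_exponential(self):
        fit = fit_exponential_decay({2: 1000, 3: 100, 4: 10, 5: 1})
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-math.log(10))

    def test_flat_counts(self):
        fit = fit_exponential_decay({2: 5, 3: 5, 4: 5})
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0)

    def test_bins_below_two_ignored(self):
        with_low = fit_exponential_decay({1: 99999, 2: 100, 3: 10, 4: 1})
        without = fit_exponential_decay({2: 100, 3: 10, 4: 1})
        assert with_low.slope == pytest.approx(without.slope)

    def test_size_error(self):
        with pytest.raises(SizeError):
            fit_exponential_decay({2: 5, 3: 5})

    def test_slope_recovery_on_geometric_counts(self):
        # histogram of a geometric length model across several seeds
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ls = 2 + rng.geometric(0.55, size=20000) - 1
            counts = {int(k): int(c) for k, c in zip(*np.unique(ls, return_counts=True))}
            fit = fit_exponential_decay(counts, min_count=10)
            assert fit.slope == pytest.approx(math.log(1 - 0.55), abs=0.05)


class TestBetweenness:
    def test_path_triangle_star(self):
        path = betweenness(undirected([("A", "B"), ("B", "C")]))
        assert path == {"A": 0.0, "B": 1.0, "C": 0.0}
        tri = betweenness(undirected([("A", "B"), ("B", "C"), ("A", "C")]))
        assert set(tri.values()) == {0.0}
        star = betweenness(undirected([("H", c) for c in "ABCD"]))
        assert star["H"] == pytest.approx(6.0)


class TestHits:
    def test_two_target_closed_form(self):
        hub, auth = hits_scores(directed([("a", "b"), ("a", "c")]))
        assert hub["a"] == pytest.approx(1.0)
        assert hub["b"] == hub["c"] == pytest.approx(0.0)
        assert auth["b"] == auth["c"] == pytest.approx(1 / math.sqrt(2))

    def test_symmetry_on_cycle_and_disjoint_edges(self):
        hub, auth = hits_scores(directed([("a", "b"), ("b", "a")]))
        assert hub["a"] == pytest.approx(hub["b"])
        assert auth["a"] == pytest.approx(auth["b"])
        hub2, _ = hits_scores(directed([("a", "b"), ("c", "d")]))
        assert hub2["a"] == pytest.approx(hub2["c"])

    def test_agrees_with_networkx_reference(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(12, 0.3, seed=4, directed=True)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = DomainNetwork(g, directed=True)
        hub, auth = hits_scores(net)
        ref_hub, ref_auth = nx.hits(g, max_iter=1000, tol=1e-12)
        # same direction up to normalization
        scale = max(ref_hub.values()) and hub[max(ref_hub, key=ref_hub.get)] / max(ref_hub.values())
        for n in g.nodes:
            assert hub[n] == pytest.approx(ref_hub[n] * scale, abs=1e-6)

    def test_error_contracts(self):
        with pytest.raises(UsageError):
            hits_scores(undirected([("a", "b")]))
        with pytest.raises(DegenerateError):
            hits_scores(directed([], nodes=["a", "b"]))

    def test_invariant_under_relabeling(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")]
        hub1, _ = hits_scores(directed(edges))
        mapping = {"a": "w", "b": "x", "c": "y", "d": "z"}
        hub2, _ = hits_scores(directed([(mapping[u], mapping[v]) for u, v in edges]))
        for k, v in mapping.items():
            assert hub1[k] == pytest.approx(hub2[v])


class TestCliquesAndBiconnectivity:
    def test_triangle_and_path_cliques(self):
        assert maximal_cliques(undirected([("A", "B"), ("B", "C"), ("A", "C")])) == [["A", "B", "C"]]
        assert maximal_cliques(undirected([("A", "B"), ("B", "C")])) == [["A", "B"], ["B", "C"]]

    def test_merge_two_triangles_sharing_vertex(self):
        net = undirected([("A", "B"), ("B", "C"), ("A", "C"),
                          ("C", "D"), ("D", "E"), ("C", "E")])
        sub = merge_largest_cliques(net, 3)
        assert sorted(sub.nodes) == ["A", "B", "C", "D", "E"]
        assert len(merge_largest_cliques(net, 4)) == 0

    def test_min_size_contract(self):
        with pytest.raises(UsageError):
            merge_largest_cliques(undirected([("A", "B")]), 1)

    def test_triangle_with_pendant(self):
        net = undirected([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        assert sorted(largest_biconnected(net).nodes) == ["A", "B", "C"]

    def test_path_tie_break_lexicographic(self):
        net = undirected([("B", "C"), ("A", "B"), ("C", "D")])
        assert sorted(largest_biconnected(net).nodes) == ["A", "B"]

    def test_empty_graph(self):
        assert len(largest_biconnected(undirected([]))) == 0

    def test_reported_component_survives_any_single_removal(self, small_corpus):
        from polyvalent.networks import build_cooccurrence_network

        net = build_cooccurrence_network(small_corpus.table)
        sub = largest_biconnected(net)
        assert len(sub) >= 2
        for v in list(sub.nodes):
            rest = sub.subgraph(n for n in sub.nodes if n != v)
            assert nx.is_connected(rest)

    def test_brute_force_equivalence_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            p = float(rng.uniform(0.2, 0.6))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            net = DomainNetwork(g, directed=False)
            nodes, edges = list(g.nodes), list(g.edges)
            assert maximal_cliques(net) == brute_force_maximal_cliques(nodes, edges)
            bc = betweenness(net)
            oracle_bc = brute_force_betweenness(nodes, edges)
            for v in nodes:
                assert bc[v] == pytest.approx(oracle_bc[v], abs=1e-9)
            if edges:
                expected = brute_force_biconnected_sets(nodes, edges)[0]
                assert sorted(largest_biconnected(net).nodes) == expected
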