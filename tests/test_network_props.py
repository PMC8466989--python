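import dataclasses
import itertools
import math

import networkx as nx
import numpy as np
import pytest

from cryonet.io_model import CooccurrenceNetwork, CryonetError
from cryonet.network_props import (
    detect_modules,
    modularity_of,
    ModulePartition,
    random_ensemble,
    topology_report,
)
from conftest import make_network


def newman_girvan_q(graph: nx.Graph, assignment: dict) -> float:
    """Independent modularity oracle: Q = sum_c (e_c/m - (d_c/2m)^2)."""
    m = graph.number_of_edges()
    q = 0.0
    for c in set(assignment.values()):
        members = {n for n, cc in assignment.items() if cc == c}
        e_c = sum(1 for u, v in graph.edges if u in members and v in members)
        d_c = sum(d for n, d in graph.degree if n in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def exhaustive_best_partition(graph: nx.Graph):
    """Brute-force max-modularity partition over all set partitions."""
    nodes = list(graph.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
            yield [[first]] + smaller

    best_q, best = -1.0, None
    for part in partitions(nodes):
        assignment = {n: i for i, block in enumerate(part) for n in block}
        q = newman_girvan_q(graph, assignment)
        if q > best_q:
            best_q, best = q, part
    return best_q, best


class TestTopologyReport:
    def test_triangle(self, triangle):
        rep = topology_report(triangle)
        assert rep.apl == pytest.approx(1.0)
        assert rep.diameter == 1
        assert rep.clustering_coefficient == pytest.approx(1.0)
        assert rep.edge_density == pytest.approx(1.0)
        assert rep.degree_mean == pytest.approx(2.0)

    def test_path3(self, path3):
        rep = topology_report(path3)
        assert rep.apl == pytest.approx(4 / 3)
        assert rep.diameter == 2
        assert rep.clustering_coefficient == 0.0

    def test_star(self):
        net = make_network([("c", "l1", 0.9), ("c", "l2", 0.9), ("c", "l3", 0.9)])
        rep = topology_report(net)
        assert rep.clustering_coefficient == 0.0
        # center lies on the 3 shortest paths between leaf pairs
        import igraph as ig

        g = ig.Graph(n=4, edges=[(0, 1), (0, 2), (0, 3)])
        assert g.betweenness()[0] == 3
        assert rep.betweenness_mean == pytest.approx(3 / 4)

    def test_identities_on_random_graphs(self, rng):
        for _ in range(5):
            g = nx.gnm_random_graph(30, 60, seed=int(rng.integers(1e6)))
            g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
            g = nx.relabel_nodes(g, str)
            nx.set_edge_attributes(g, 0.8, "rho")
            nx.set_edge_attributes(g, "+", "sign")
            net = CooccurrenceNetwork(g)
            rep = topology_report(net)
            n, e = rep.n_nodes, rep.n_edges
            assert rep.degree_mean == pytest.approx(2 * e / n)
            assert rep.edge_density == pytest.approx(2 * e / (n * (n - 1)))
            assert rep.n_significant_correlations == 2 * e
            assert rep.diameter >= rep.apl
            assert -0.5 <= rep.modularity <= 1.0

    def test_counts_match_table_identities(self):
        # a graph with the topsoil column's printed totals reproduces its
        # printed mean degree and edge density
        g = nx.circulant_graph(476, [1, 2, 3])  # 476 nodes, 1428 edges
        extra = [(i, (i + 5) % 476) for i in range(99)]
        g.add_edges_from(extra)
        assert g.number_of_edges() == 1527
        g = nx.relabel_nodes(g, str)
        nx.set_edge_attributes(g, 0.7, "rho")
        nx.set_edge_attributes(g, "+", "sign")
        rep = topology_report(CooccurrenceNetwork(g))
        assert round(rep.degree_mean, 2) == 6.42
        assert round(rep.edge_density, 4) == 0.0135


class TestDetectModules:
    def test_two_cliques_match_exhaustive_oracle(self, two_cliques):
        part = detect_modules(two_cliques, "greedy")
        best_q, best_blocks = exhaustive_best_partition(two_cliques.graph)
        # clique partition: Q = 12/13 - 2 * (13/26)^2 = 11/26
        assert best_q == pytest.approx(11 / 26)
        assert part.modularity == pytest.approx(best_q)
        blocks = {frozenset(part.members(m)) for m in range(1, part.n_modules + 1)}
        assert blocks == {frozenset(b) for b in best_blocks}
        # Q agrees with the independent formula
        assert part.modularity == pytest.approx(
            newman_girvan_q(two_cliques.graph, part.assignment)
        )

    def test_complete_graph_single_module(self):
        edges = [(f"n{i}", f"n{j}", 0.9) for i in range(5) for j in range(i + 1, 5)]
        net = make_network(edges)
        part = detect_modules(net, "greedy")
        assert part.n_modules == 1
        assert part.modularity == pytest.approx(0.0)

    def test_deterministic(self, two_cliques):
        a = detect_modules(two_cliques, "greedy", seed=7)
        b = detect_modules(two_cliques, "greedy", seed=7)
        assert a.assignment == b.assignment
        l1 = detect_modules(two_cliques, "louvain", seed=3)
        l2 = detect_modules(two_cliques, "louvain", seed=3)
        assert l1.assignment == l2.assignment

    def test_module_one_is_largest(self, rng):
        g = nx.gnm_random_graph(40, 80, seed=5)
        g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
        g = nx.relabel_nodes(g, str)
        nx.set_edge_attributes(g, 0.7, "rho")
        part = detect_modules(CooccurrenceNetwork(g))
        sizes = part.module_sizes()
        ordered = [sizes[m] for m in sorted(sizes)]
        assert ordered == sorted(ordered, reverse=True)

    def test_modularity_of_cross_check(self, two_cliques, rng):
        nodes = list(two_cliques.graph.nodes)
        assignment = {n: int(rng.integers(0, 3)) for n in nodes}
        part = ModulePartition(assignment, 0.0, "manual")
        assert modularity_of(two_cliques, part) == pytest.approx(
            newman_girvan_q(two_cliques.graph, assignment)
        )


class TestRandomEnsemble:
    def test_forced_complete_graph(self):
        out = random_ensemble(4, 6, reps=20, seed=1)
        assert out.apl_mean == pytest.approx(1.0)
        assert out.apl_sd == 0.0
        assert out.cc_mean == pytest.approx(1.0)

    def test_infeasible_edge_count(self):
        with pytest.raises(CryonetError, match="infeasible"):
            random_ensemble(4, 7, reps=5, seed=1)

    def test_deterministic_given_seed(self):
        a = random_ensemble(30, 60, reps=10, seed=42)
        b = random_ensemble(30, 60, reps=10, seed=42)
        assert a == b

    def test_cc_converges_to_density(self):
        # ER expectation: transitivity -> p = 2m / (n(n-1))
        n, m = 340, 1227
        out = random_ensemble(n, m, reps=60, seed=3)
        density = 2 * m / (n * (n - 1))
        assert abs(out.cc_mean - density) < 3 * out.cc_sd / math.sqrt(out.reps) + 0.001

    def test_sds_nonnegative(self):
        out = random_ensemble(50, 100, reps=10, seed=0)
        assert out.apl_sd >= 0 and out.cc_sd >= 0 and out.modularity_sd >= 0


class TestEmpiricalVsNull:
    def test_paper_like_modularity_beats_null(self):
        """Each synthetic network's modularity exceeds its ER null mean."""
        from cryonet.network_build import spearman_matrix, build_network
        from cryonet.preprocess import FilterParams, filter_taxa, relative_abundance
        from cryonet.synthetic import default_paper_like_spec, simulate_community

        spec = default_paper_like_spec()
        for seed in range(10):
            table, meta, *_ = simulate_community(dataclasses.replace(spec, seed=seed))
            samples = meta.samples_in_group("horizon", "topsoil")
            filt = filter_taxa(relative_abundance(table), FilterParams(), samples)
            net = build_network(spearman_matrix(filt))
            part = detect_modules(net)
            null = random_ensemble(net.n_nodes, net.n_edges, reps=10, seed=seed)
            assert part.modularity > null.modularity_mean
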