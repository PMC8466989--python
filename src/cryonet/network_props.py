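"""Topological property report, modularity-based module detection, and the
seeded Erdos-Renyi G(n, m) null ensemble.

Conventions (chosen to match igraph, whose output the reported metric scales
correspond to):

* APL averages shortest-path lengths over connected ordered pairs only.
* The clustering coefficient is global transitivity (3 * triangles divided by
  connected triples).
* Closeness is computed per node within its own connected component and
  summarized as mean +/- sd of its natural log (the untransformed mean is
  also emitted); betweenness is unnormalized.
* The null model fixes the edge COUNT — uniform simple G(n, m) — not the
  edge probability.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import random
from typing import Sequence

import igraph as ig
import networkx as nx
import numpy as np

from .io_model import CooccurrenceNetwork, CryonetError

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ModulePartition:
    """node -> 1-based module id; module 1 is the largest.

    Ties in module size break on the smallest member node label, so the
    numbering is deterministic.
    """

    assignment: dict[str, int]
    modularity: float
    algorithm: str
    seed: int | None = None

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module_id: int) -> list[str]:
        return [n for n, m in self.assignment.items() if m == module_id]

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes


@dataclasses.dataclass
class TopologyReport:
    total_taxa_after_filter: int | None
    abundance_pct_retained: float | None
    n_significant_correlations: int
    n_nodes: int
    n_edges: int
    n_pos_edges: int
    n_neg_edges: int
    apl: float
    degree_mean: float
    degree_sd: float
    closeness_log_mean: float
    closeness_log_sd: float
    closeness_mean: float
    betweenness_mean: float
    betweenness_sd: float
    edge_density: float
    diameter: int
    clustering_coefficient: float
    clustering_avg_local: float
    n_modules: int
    modularity: float
    module_algorithm: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class NullEnsembleSummary:
    reps: int
    n_nodes: int
    n_edges: int
    apl_mean: float
    apl_sd: float
    cc_mean: float
    cc_sd: float
    modularity_mean: float
    modularity_sd: float
    seed: int
    algorithm: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _as_igraph(net: CooccurrenceNetwork | nx.Graph) -> tuple[ig.Graph, list]:
    graph = net.graph if isinstance(net, CooccurrenceNetwork) else net
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    return g, nodes


def detect_modules(
    net: CooccurrenceNetwork | nx.Graph,
    algorithm: str = "greedy",
    seed: int = 0,
) -> ModulePartition:
    """Heuristic modularity-maximizing partition of the unweighted graph.

    ``greedy`` is deterministic agglomerative (fast-greedy) optimization;
    ``louvain`` is multilevel optimization, made deterministic by the seed.
    Modularity Q is the standard Newman-Girvan value of the final partition.
    """
    g, nodes = _as_igraph(net)
    if g.vcount() < 1:
        raise CryonetError("cannot partition an empty graph")
    if algorithm == "greedy":
        clustering = g.community_fastgreedy().as_clustering()
    elif algorithm == "louvain":
        state = random.getstate()
        try:
            random.seed(seed)
            clustering = g.community_multilevel()
        finally:
            random.setstate(state)
    else:
        raise CryonetError(f"unknown module algorithm {algorithm!r}")
    q = float(g.modularity(clustering.membership))
    groups: dict[int, list] = {}
    for node, community in zip(nodes, clustering.membership):
        groups.setdefault(community, []).append(node)
    ordered = sorted(
        groups.values(), key=lambda members: (-len(members), min(map(str, members)))
    )
    assignment = {n: i + 1 for i, members in enumerate(ordered) for n in members}
    return ModulePartition(assignment, q, algorithm, seed)


def modularity_of(net: CooccurrenceNetwork | nx.Graph, partition: ModulePartition) -> float:
    """Newman-Girvan modularity of an arbitrary partition (for cross-checks)."""
    g, nodes = _as_igraph(net)
    membership = [partition.assignment[n] for n in nodes]
    return float(g.modularity(membership))


def _apl_cc(g: ig.Graph) -> tuple[float, float]:
    apl = g.average_path_length(directed=False, unconn=True)
    cc = g.transitivity_undirected(mode="zero")
    return float(apl), float(cc)


def topology_report(
    net: CooccurrenceNetwork,
    partition: ModulePartition | None = None,
    total_taxa_after_filter: int | None = None,
    abundance_pct_retained: float | None = None,
    algorithm: str = "greedy",
    seed: int = 0,
) -> TopologyReport:
    if net.n_nodes < 2:
        raise CryonetError("topology report needs at least 2 nodes")
    if partition is None:
        partition = detect_modules(net, algorithm=algorithm, seed=seed)
    g, nodes = _as_igraph(net)
    n, e = g.vcount(), g.ecount()
    pos, neg = net.edge_signs()
    degrees = np.asarray(g.degree(), dtype=float)
    apl, cc = _apl_cc(g)
    diameter = int(g.diameter(directed=False, unconn=True))
    # closeness within each node's component; igraph restricts to reachable
    # vertices via mode=ALL on disconnected graphs and warns, so compute per
    # component explicitly.
    closeness = np.empty(n)
    for comp in g.connected_components():
        if len(comp) == 1:  # cannot happen for valid networks, kept for safety
            closeness[comp[0]] = math.nan
            continue
        sub = g.subgraph(comp)
        closeness[list(comp)] = sub.closeness()
    betweenness = np.asarray(g.betweenness(directed=False), dtype=float)
    avg_local = float(g.transitivity_avglocal_undirected(mode="zero"))
    report = TopologyReport(
        total_taxa_after_filter=total_taxa_after_filter,
        abundance_pct_retained=abundance_pct_retained,
        n_significant_correlations=2 * e,
        n_nodes=n,
        n_edges=e,
        n_pos_edges=pos,
        n_neg_edges=neg,
        apl=apl,
        degree_mean=float(degrees.mean()),
        degree_sd=float(degrees.std()),
        closeness_log_mean=float(np.log(closeness).mean()),
        closeness_log_sd=float(np.log(closeness).std()),
        closeness_mean=float(closeness.mean()),
        betweenness_mean=float(betweenness.mean()),
        betweenness_sd=float(betweenness.std()),
        edge_density=2.0 * e / (n * (n - 1)),
        diameter=diameter,
        clustering_coefficient=cc,
        clustering_avg_local=avg_local,
        n_modules=partition.n_modules,
        modularity=partition.modularity,
        module_algorithm=partition.algorithm,
    )
    assert math.isclose(report.degree_mean, 2.0 * e / n)
    assert math.isclose(report.edge_density, 2.0 * e / (n * (n - 1)))
    return report


def random_ensemble(
    n_nodes: int,
    n_edges: int,
    reps: int = 1000,
    seed: int = 0,
    algorithm: str = "greedy",
) -> NullEnsembleSummary:
    """Mean +/- sd of APL, CC and modularity over uniform G(n, m) graphs.

    Each replicate is a simple graph with exactly ``n_edges`` edges (no
    self-loops or multi-edges); modularity uses the same module-detection
    algorithm as the empirical reports.
    """
    if reps < 1:
        raise CryonetError("reps must be >= 1")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise CryonetError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    apls, ccs, mods = [], [], []
    state = random.getstate()
    try:
        random.seed(seed)  # python-igraph draws from the stdlib RNG
        for _ in range(reps):
            g = ig.Graph.Erdos_Renyi(n=n_nodes, m=n_edges)
            apl, cc = _apl_cc(g)
            apls.append(apl)
            ccs.append(cc)
            if algorithm == "louvain":
                clustering = g.community_multilevel()
            else:
                clustering = g.community_fastgreedy().as_clustering()
            mods.append(float(g.modularity(clustering.membership)))
    finally:
        random.setstate(state)
    apls, ccs, mods = map(np.asarray, (apls, ccs, mods))
    return NullEnsembleSummary(
        reps=reps,
        n_nodes=n_nodes,
        n_edges=n_edges,
        apl_mean=float(apls.mean()),
        apl_sd=float(apls.std()),
        cc_mean=float(ccs.mean()),
        cc_sd=float(ccs.std()),
        modularity_mean=float(mods.mean()),
        modularity_sd=float(mods.std()),
        seed=seed,
        algorithm=algorithm,
    )
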