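"""Spearman correlation with t-approximation p-values, Benjamini-Hochberg
FDR over the upper triangle, and thresholded network construction."""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import stats

from .io_model import CooccurrenceNetwork, CryonetError, RelAbundanceTable

log = logging.getLogger(__name__)


@dataclasses.dataclass
class CorrelationResult:
    taxa_ids: list[str]
    rho: np.ndarray  # symmetric, unit diagonal
    p: np.ndarray  # symmetric, diagonal 0
    q: np.ndarray  # BH-adjusted over the upper triangle
    constant_taxa: list[str]  # zero rank variance; rho forced to 0, p to 1

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)


@dataclasses.dataclass
class EdgeThresholds:
    rho_min: float = 0.6
    p_max: float = 0.01
    use_adjusted_p: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.rho_min <= 1:
            raise CryonetError("rho_min must lie in (0, 1]")
        if not 0 < self.p_max <= 1:
            raise CryonetError("p_max must lie in (0, 1]")


def spearman_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via t = rho*sqrt((n-2)/(1-rho^2)), df = n-2.

    |rho| = 1 maps to p = 0.
    """
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.clip(p, 0.0, 1.0)


def spearman_matrix(rel: RelAbundanceTable) -> CorrelationResult:
    """All-pairs tie-aware Spearman rho (Pearson on average ranks) with p.

    Constant taxa (zero rank variance) cannot be correlated: their entries are
    recorded as rho = 0, p = 1 and the taxa are flagged.
    """
    values = rel.values
    m, n = values.shape
    if n < 5:
        raise CryonetError(f"need at least 5 samples, got {n}")
    ranks = np.apply_along_axis(stats.rankdata, 1, values)  # average ranks
    sd = ranks.std(axis=1)
    constant = sd == 0
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1))
    denom[constant] = 1.0  # avoid 0/0; rows zeroed below
    normed = centered / denom[:, np.newaxis]
    rho = normed @ normed.T
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    p = spearman_pvalues(rho, n)
    np.fill_diagonal(p, 0.0)
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    iu = np.triu_indices(m, k=1)
    q = np.ones_like(p)
    q_upper = bh_adjust(p[iu])
    q[iu] = q_upper
    q = np.minimum(q, q.T)
    np.fill_diagonal(q, 0.0)
    flagged = [t for t, c in zip(rel.taxa_ids, constant) if c]
    if flagged:
        log.info("constant taxa excluded from correlation: %d", len(flagged))
    return CorrelationResult(list(rel.taxa_ids), rho, p, q, flagged)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q(i) = min_{j >= i, sorted} p(j) * m / j, clipped at 1; order-preserving.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise CryonetError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def build_network(
    corr: CorrelationResult,
    thresholds: EdgeThresholds | None = None,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> CooccurrenceNetwork:
    """Threshold the correlation matrix into an undirected signed network.

    Edge (i, j) exists iff |rho_ij| >= rho_min and the (adjusted, by default)
    p-value is < p_max. Taxa with no retained edge are not nodes.
    """
    thresholds = thresholds or EdgeThresholds()
    pmat = corr.q if thresholds.use_adjusted_p else corr.p
    graph = nx.Graph()
    m = corr.n_taxa
    iu, ju = np.triu_indices(m, k=1)
    strong = (np.abs(corr.rho[iu, ju]) >= thresholds.rho_min) & (
        pmat[iu, ju] < thresholds.p_max
    )
    for i, j in zip(iu[strong], ju[strong]):
        rho = float(corr.rho[i, j])
        graph.add_edge(
            corr.taxa_ids[i],
            corr.taxa_ids[j],
            rho=rho,
            sign="+" if rho >= 0 else "-",
        )
    if node_attrs:
        for taxon in graph.nodes:
            for key, mapping in node_attrs.items():
                if taxon in mapping:
                    graph.nodes[taxon][key] = mapping[taxon]
    net = CooccurrenceNetwork(graph)
    pos, neg = net.edge_signs()
    log.info(
        "network: %d nodes, %d edges (%d positive, %d negative)",
        net.n_nodes,
        net.n_edges,
        pos,
        neg,
    )
    return net


def significant_pairs(
    corr: CorrelationResult, thresholds: EdgeThresholds | None = None
):
    """Long-format table of all retained pairs (taxon_i, taxon_j, rho, p, q)."""
    import pandas as pd

    thresholds = thresholds or EdgeThresholds()
    pmat = corr.q if thresholds.use_adjusted_p else corr.p
    rows = []
    m = corr.n_taxa
    for i in range(m):
        for j in range(i + 1, m):
            if abs(corr.rho[i, j]) >= thresholds.rho_min and pmat[i, j] < thresholds.p_max:
                rows.append(
                    (
                        corr.taxa_ids[i],
                        corr.taxa_ids[j],
                        corr.rho[i, j],
                        corr.p[i, j],
                        corr.q[i, j],
                    )
                )
    return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "rho", "p", "q"])
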