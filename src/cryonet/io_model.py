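"""Core data model and readers/writers for tabular and graph artifacts.

The canonical orientation for abundance tables is taxa x samples. Networks
are simple undirected graphs whose nodes are taxa and whose edges carry the
Spearman correlation (``rho``) and its sign.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

HORIZONS = ("topsoil", "cryoOM", "subsoil", "permafrost")
SITES = (1, 2, 3, 4)

#: Environmental factors carried by sample metadata, in canonical order.
ENV_FACTORS = (
    "moisture",
    "pH",
    "DOC",
    "DN",
    "Ctot",
    "Ntot",
    "CN",
    "BG",
    "CBH",
    "LAP",
    "NAG",
)

#: Taxonomic ranks, stored positionally.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

UNASSIGNED = "unassigned"


class CryonetError(ValueError):
    """Base class for validation errors raised by this package."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise CryonetError(f"duplicate id in {what}: {i!r}")
        seen.add(i)
    return ids


@dataclasses.dataclass
class ZOTUTable:
    """Sparse nonnegative count matrix, taxa x samples."""

    taxa_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxa_ids = _check_unique(self.taxa_ids, "taxa")
        self.sample_ids = _check_unique(self.sample_ids, "samples")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise CryonetError(
                f"count matrix shape {self.counts.shape} does not match "
                f"({len(self.taxa_ids)}, {len(self.sample_ids)})"
            )
        if len(self.taxa_ids) < 1 or len(self.sample_ids) < 2:
            raise CryonetError("need at least 1 taxon and 2 samples")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise CryonetError("counts must be numeric")
        if np.any(self.counts < 0):
            raise CryonetError("negative counts")
        if np.any(self.counts != np.floor(self.counts)):
            raise CryonetError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa_ids, columns=self.sample_ids)


@dataclasses.dataclass
class RelAbundanceTable:
    """Per-sample fractional abundances on the same axes as :class:`ZOTUTable`.

    Column sums equal 1 immediately after normalization; the abundance filter
    deliberately does NOT renormalize, so filtered tables sum to < 1.
    """

    taxa_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.taxa_ids = _check_unique(self.taxa_ids, "taxa")
        self.sample_ids = _check_unique(self.sample_ids, "samples")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise CryonetError("value matrix shape mismatch")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-9):
            raise CryonetError("relative abundances must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Iterable[str]) -> "RelAbundanceTable":
        sample_ids = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return RelAbundanceTable(list(self.taxa_ids), sample_ids, self.values[:, idx])


class SampleMetadata:
    """Per-sample stratum labels and environmental factors.

    Backed by a DataFrame indexed by sample id with columns ``horizon``,
    ``site`` and the 11 factors in :data:`ENV_FACTORS`. Missing factor values
    are stored as NaN and pairwise-deleted in correlations.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.has_duplicates:
            raise CryonetError("duplicate sample id in metadata")
        for col in ("horizon", "site"):
            if col not in frame.columns:
                raise CryonetError(f"metadata missing column {col!r}")
        bad = set(frame["horizon"]) - set(HORIZONS)
        if bad:
            raise CryonetError(f"unknown horizon label(s): {sorted(bad)}")
        frame["site"] = frame["site"].astype(int)
        bad_sites = set(frame["site"]) - set(SITES)
        if bad_sites:
            raise CryonetError(f"unknown site label(s): {sorted(bad_sites)}")
        for f in ENV_FACTORS:
            if f not in frame.columns:
                frame[f] = np.nan
            frame[f] = pd.to_numeric(frame[f])
        ph = frame["pH"].dropna()
        if ((ph < 0) | (ph > 14)).any():
            raise CryonetError("pH out of [0, 14]")
        moist = frame["moisture"].dropna()
        if ((moist < 0) | (moist > 100)).any():
            raise CryonetError("moisture out of [0, 100]")
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = set(sample_ids) - set(self.frame.index)
        if missing:
            raise CryonetError(f"samples without metadata: {sorted(missing)}")

    def samples_in_group(self, variable: str, level) -> list[str]:
        if variable not in ("horizon", "site"):
            raise CryonetError(f"unknown grouping variable {variable!r}")
        col = self.frame[variable]
        if variable == "site":
            level = int(level)
        return list(self.frame.index[col == level])

    def env(self, factor: str) -> pd.Series:
        if factor not in ENV_FACTORS:
            raise CryonetError(f"unknown environmental factor {factor!r}")
        return self.frame[factor]


class TaxonomyTable:
    """taxon_id -> positional 7-rank lineage; unknown ranks are 'unidentified'."""

    def __init__(self, lineages: Mapping[str, tuple]):
        self._ranks: dict[str, tuple[str, ...]] = {}
        for taxon, lineage in lineages.items():
            lineage = tuple(lineage)
            if len(lineage) > len(RANKS):
                raise CryonetError(f"lineage for {taxon} has more than 7 ranks")
            lineage = lineage + ("unidentified",) * (len(RANKS) - len(lineage))
            self._ranks[taxon] = lineage

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._ranks

    def lineage(self, taxon: str) -> tuple[str, ...]:
        return self._ranks.get(taxon, ("unidentified",) * len(RANKS))

    def rank(self, taxon: str, rank: str) -> str:
        return self.lineage(taxon)[RANKS.index(rank)]

    def genus(self, taxon: str) -> str:
        return self.rank(taxon, "genus")

    def items(self):
        return self._ranks.items()


class TraitsTable:
    """genus -> (lifestyle, trophic_mode), FungalTraits style.

    Genera absent from the table map to ``"unassigned"``.
    """

    def __init__(self, rows: Mapping[str, tuple[str, str]]):
        self._rows = {g: (str(l), str(t)) for g, (l, t) in rows.items()}

    def lifestyle(self, genus: str) -> str:
        return self._rows.get(genus, (UNASSIGNED, UNASSIGNED))[0]

    def trophic_mode(self, genus: str) -> str:
        return self._rows.get(genus, (UNASSIGNED, UNASSIGNED))[1]

    def items(self):
        return self._rows.items()


class CooccurrenceNetwork:
    """Simple undirected graph over taxa with rho-weighted signed edges.

    Wraps a :class:`networkx.Graph`; node attributes are ``abundance`` (mean
    relative abundance) and ``lifestyle``, plus ``module``/``zi``/``pi``/
    ``role`` once downstream stages have run. Isolated nodes never occur: a
    taxon is only a node if it has at least one retained edge.
    """

    def __init__(self, graph: nx.Graph):
        if nx.number_of_selfloops(graph):
            raise CryonetError("self-loops are not allowed")
        isolated = [n for n, d in graph.degree() if d == 0]
        if isolated:
            raise CryonetError(f"isolated nodes are not allowed: {isolated[:5]}")
        for u, v, data in graph.edges(data=True):
            if "rho" not in data:
                raise CryonetError(f"edge ({u}, {v}) missing rho")
            data.setdefault("sign", "+" if data["rho"] >= 0 else "-")
        self.graph = graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_signs(self) -> tuple[int, int]:
        """(positive, negative) edge counts."""
        pos = sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] == "+")
        return pos, self.n_edges - pos

    def __eq__(self, other) -> bool:
        if not isinstance(other, CooccurrenceNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        if set(map(frozenset, self.graph.edges)) != set(map(frozenset, other.graph.edges)):
            return False
        for u, v, d in self.graph.edges(data=True):
            if not math.isclose(d["rho"], other.graph[u][v]["rho"], abs_tol=1e-12):
                return False
        return True


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_zotu_table(path, orientation: str = "taxa_rows") -> ZOTUTable:
    """Read a TSV/CSV count table with one header row and one id column.

    ``orientation`` names what the ROWS are: ``taxa_rows`` (canonical) or
    ``samples_rows`` (transposed input).
    """
    frame = _read_table(path)
    if orientation == "samples_rows":
        frame = frame.T
    elif orientation != "taxa_rows":
        raise CryonetError(f"unknown orientation {orientation!r}")
    try:
        counts = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise CryonetError(f"non-numeric counts in {path}: {exc}") from exc
    if np.isnan(counts).any():
        raise CryonetError(f"missing/ragged values in {path}")
    return ZOTUTable(
        [str(i) for i in frame.index], [str(c) for c in frame.columns], counts
    )


def write_zotu_table(table: ZOTUTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def write_rel_abundance(rel: RelAbundanceTable, path) -> None:
    rel.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def read_rel_abundance(path) -> RelAbundanceTable:
    frame = _read_table(path)
    return RelAbundanceTable(
        [str(i) for i in frame.index],
        [str(c) for c in frame.columns],
        frame.to_numpy(dtype=float),
    )


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(_read_table(path))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def _split_lineage(s: str) -> tuple[str, ...]:
    parts = [p.strip() for p in str(s).split(";")]
    out = []
    for p in parts:
        # tolerate UNITE-style "g__Genus" prefixes
        if len(p) > 2 and p[1:3] == "__":
            p = p[3:]
        out.append(p if p else "unidentified")
    return tuple(out)


def read_taxonomy(path) -> TaxonomyTable:
    """Read taxon_id<TAB>lineage, lineage semicolon-delimited (k__ optional)."""
    frame = _read_table(path)
    col = frame.columns[0]
    return TaxonomyTable({str(t): _split_lineage(frame.loc[t, col]) for t in frame.index})


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    rows = {t: ";".join(lin) for t, lin in tax.items()}
    pd.Series(rows, name="lineage").to_csv(path, sep="\t", index_label="taxon_id")


def read_traits(path) -> TraitsTable:
    frame = _read_table(path)
    need = {"lifestyle", "trophic_mode"}
    if not need <= set(frame.columns):
        raise CryonetError(f"traits table must have columns {sorted(need)}")
    return TraitsTable(
        {str(g): (frame.loc[g, "lifestyle"], frame.loc[g, "trophic_mode"]) for g in frame.index}
    )


def write_traits(traits: TraitsTable, path) -> None:
    frame = pd.DataFrame(
        [(g, l, t) for g, (l, t) in traits.items()],
        columns=["genus", "lifestyle", "trophic_mode"],
    ).set_index("genus")
    frame.to_csv(path, sep="\t")


def write_network(net: CooccurrenceNetwork, path, format: str = "graphml") -> None:
    if net.n_edges == 0:
        raise CryonetError("refusing to write an empty network")
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edge_tsv":
        rows = [
            (u, v, repr(d["rho"]), d["sign"]) for u, v, d in net.graph.edges(data=True)
        ]
        frame = pd.DataFrame(rows, columns=["source", "target", "rho", "sign"])
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise CryonetError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> CooccurrenceNetwork:
    path = Path(path)
    if format == "graphml":
        graph = nx.read_graphml(path)
        graph = nx.Graph(graph)
    elif format == "edge_tsv":
        frame = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        graph = nx.Graph()
        for row in frame.itertuples(index=False):
            graph.add_edge(row.source, row.target, rho=float(row.rho), sign=row.sign)
    else:
        raise CryonetError(f"unknown network format {format!r}")
    return CooccurrenceNetwork(graph)


def assign_lifestyles(
    table: ZOTUTable, tax: TaxonomyTable, traits: TraitsTable
) -> dict[str, str]:
    """Map every taxon to a lifestyle label via its genus.

    Taxa with an unidentified genus, or whose genus is absent from the traits
    table, map to ``"unassigned"``.
    """
    out = {}
    for taxon in table.taxa_ids:
        genus = tax.genus(taxon)
        out[taxon] = UNASSIGNED if genus == "unidentified" else traits.lifestyle(genus)
    return out


def assign_trophic_modes(
    table: ZOTUTable, tax: TaxonomyTable, traits: TraitsTable
) -> dict[str, str]:
    out = {}
    for taxon in table.taxa_ids:
        genus = tax.genus(taxon)
        out[taxon] = UNASSIGNED if genus == "unidentified" else traits.trophic_mode(genus)
    return out
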