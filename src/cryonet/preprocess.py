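"""Relative-abundance normalization, prevalence/abundance filtering, and
alpha-diversity indices.

The filter keeps a taxon when it is present (count > 0) in strictly more than
``prevalence_min`` of the samples under consideration AND its mean relative
abundance over those samples is at least ``mean_abund_min``. Values are not
renormalized after rows are dropped, so the surviving column sums report the
fraction of community abundance retained.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io_model import CryonetError, RelAbundanceTable, ZOTUTable

log = logging.getLogger(__name__)


@dataclasses.dataclass
class FilterParams:
    prevalence_min: float = 0.30  # strict >
    mean_abund_min: float = 0.001  # >=
    abundance_rule: str = "mean"  # or "max"

    def __post_init__(self) -> None:
        for v in (self.prevalence_min, self.mean_abund_min):
            if not 0 <= v < 1:
                raise CryonetError("filter thresholds must lie in [0, 1)")
        if self.abundance_rule not in ("mean", "max"):
            raise CryonetError("abundance_rule must be 'mean' or 'max'")


def relative_abundance(table: ZOTUTable) -> RelAbundanceTable:
    totals = table.counts.sum(axis=0)
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise CryonetError(f"all-zero sample(s): {bad}")
    values = table.counts / totals[np.newaxis, :]
    return RelAbundanceTable(list(table.taxa_ids), list(table.sample_ids), values)


def filter_taxa(
    rel: RelAbundanceTable,
    params: FilterParams | None = None,
    sample_subset: list[str] | None = None,
) -> RelAbundanceTable:
    """Drop low-prevalence / low-abundance taxa, restricted to a sample subset.

    Restriction happens FIRST: prevalence and abundance are both evaluated on
    the subset's columns only, and the returned table contains only those
    columns. Rows are dropped without renormalizing.
    """
    params = params or FilterParams()
    if sample_subset is not None:
        if not sample_subset:
            raise CryonetError("sample subset is empty")
        rel = rel.subset_samples(sample_subset)
    values = rel.values
    n = values.shape[1]
    prevalence = (values > 0).sum(axis=1) / n
    if params.abundance_rule == "mean":
        abundance = values.mean(axis=1)
    else:
        abundance = values.max(axis=1)
    keep = (prevalence > params.prevalence_min) & (abundance >= params.mean_abund_min)
    if not keep.any():
        log.warning("filter_taxa retained no taxa")
    taxa = [t for t, k in zip(rel.taxa_ids, keep) if k]
    return RelAbundanceTable(taxa, list(rel.sample_ids), values[keep])


def abundance_retained(filtered: RelAbundanceTable) -> float:
    """Mean fraction of per-sample abundance retained after filtering (%)."""
    if filtered.shape[0] == 0:
        return 0.0
    return float(filtered.values.sum(axis=0).mean() * 100.0)


def chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness; bias-corrected form by default (defined when f2 = 0)."""
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise CryonetError("classic Chao1 undefined when there are no doubletons")
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(counts: np.ndarray) -> float:
    """Shannon diversity in nats."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise CryonetError("all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson_evenness(counts: np.ndarray) -> float:
    """Inverse-Simpson diversity divided by observed richness, in (0, 1]."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise CryonetError("all-zero sample")
    p = counts[counts > 0] / total
    s_obs = p.size
    return float(1.0 / (p**2).sum() / s_obs)


def alpha_diversity(table: ZOTUTable) -> pd.DataFrame:
    """Per-sample Chao1, Shannon (nats) and Simpson evenness."""
    rows = []
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[:, j]
        if col.sum() == 0:
            raise CryonetError(f"all-zero sample: {sample}")
        rows.append(
            {
                "sample_id": sample,
                "chao1": chao1(col),
                "shannon": shannon(col),
                "simpson_evenness": simpson_evenness(col),
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    assert (out["chao1"] + 1e-9 >= (table.counts > 0).sum(axis=0)).all()
    assert (out["shannon"] >= 0).all()
    assert ((out["simpson_evenness"] > 0) & (out["simpson_evenness"] <= 1 + 1e-12)).all()
    return out
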