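"""Module lifestyle composition and Spearman correlation of module profiles /
keystone taxa against log-transformed environmental factors.

A module's per-sample variable is the SUM of its member taxa's relative
abundances (abundance-weighted; ``mean`` and ``presence`` alternatives are
available and labeled in the output). Environmental factors are transformed
ln(x + eps) with eps = half the smallest positive observed value per factor;
pH is exempt because it is already a log scale. Stars mark raw p-values
(no multiple-testing adjustment): ``**`` for p < 0.01, ``*`` for p < 0.05.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    ENV_FACTORS,
    CooccurrenceNetwork,
    CryonetError,
    RelAbundanceTable,
    SampleMetadata,
    UNASSIGNED,
)
from .network_build import spearman_pvalues
from .network_props import ModulePartition

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ModuleProfile:
    module_id: int
    n_nodes: int
    abundance: pd.Series  # per-sample aggregate relative abundance
    lifestyle_composition: dict[str, float]  # node-count fractions, sums to 1


def stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def module_profiles(
    net: CooccurrenceNetwork,
    partition: ModulePartition,
    rel: RelAbundanceTable,
    lifestyles: Mapping[str, str] | None = None,
    top_k: int = 5,
    aggregate: str = "sum",
) -> list[ModuleProfile]:
    """Per-sample abundance profile and lifestyle composition of the top-k
    modules by node count (ties break toward the lower module id)."""
    if aggregate not in ("sum", "mean", "presence"):
        raise CryonetError("aggregate must be 'sum', 'mean' or 'presence'")
    missing = set(partition.assignment) - set(rel.taxa_ids)
    if missing:
        raise CryonetError(f"partitioned taxa absent from table: {sorted(missing)[:5]}")
    frame = rel.to_frame()
    sizes = partition.module_sizes()
    # module ids are size-ordered at construction; sort again defensively
    chosen = sorted(sizes, key=lambda m: (-sizes[m], m))[:top_k]
    profiles = []
    for module_id in chosen:
        members = partition.members(module_id)
        block = frame.loc[members]
        if aggregate == "sum":
            series = block.sum(axis=0)
        elif aggregate == "mean":
            series = block.mean(axis=0)
        else:
            series = (block > 0).sum(axis=0).astype(float)
        series.name = f"module_{module_id}"
        comp: dict[str, float] = {}
        for taxon in members:
            label = (lifestyles or {}).get(taxon, UNASSIGNED)
            comp[label] = comp.get(label, 0.0) + 1.0
        comp = {k: v / len(members) for k, v in comp.items()}
        profiles.append(
            ModuleProfile(
                module_id=module_id,
                n_nodes=len(members),
                abundance=series,
                lifestyle_composition=comp,
            )
        )
    return profiles


def log_transform_env(meta: SampleMetadata) -> pd.DataFrame:
    """ln(x + eps) per factor with eps = half the smallest positive value;
    pH passed through unchanged. Missing values stay missing."""
    out = {}
    for factor in ENV_FACTORS:
        series = meta.env(factor)
        if factor == "pH":
            out[factor] = series.astype(float)
            continue
        positive = series[series > 0]
        eps = positive.min() / 2.0 if len(positive) else 1.0
        out[factor] = np.log(series.astype(float) + eps)
    return pd.DataFrame(out)


def env_correlate(
    series_set: Mapping[str, pd.Series] | pd.DataFrame,
    meta: SampleMetadata,
    log_transform: bool = True,
    factors: Sequence[str] = ENV_FACTORS,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Long-format Spearman correlation of each series against each factor.

    Columns: row_id, factor, rho, p, stars, n, flagged. Pairwise deletion of
    missing values; a pairing with fewer than ``min_samples`` complete
    observations or a constant side is recorded as rho 0, p 1 and flagged.
    """
    if isinstance(series_set, pd.DataFrame):
        series_set = {str(c): series_set[c] for c in series_set.columns}
    env = log_transform_env(meta) if log_transform else meta.frame[list(factors)]
    rows = []
    for row_id, series in series_set.items():
        series = pd.Series(series).astype(float)
        for factor in factors:
            joined = pd.concat([series, env[factor]], axis=1, join="inner").dropna()
            x = joined.iloc[:, 0].to_numpy()
            y = joined.iloc[:, 1].to_numpy()
            n = len(joined)
            flagged = False
            if n < min_samples or np.all(x == x[0]) or np.all(y == y[0]):
                rho, p = 0.0, 1.0
                flagged = True
            else:
                rx = stats.rankdata(x)
                ry = stats.rankdata(y)
                rho = float(np.corrcoef(rx, ry)[0, 1])
                rho = float(np.clip(rho, -1.0, 1.0))
                p = float(spearman_pvalues(np.array(rho), n))
            rows.append(
                {
                    "row_id": row_id,
                    "factor": factor,
                    "rho": rho,
                    "p": p,
                    "stars": stars(p) if not flagged else "",
                    "n": n,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


def composition_frame(profiles: Sequence[ModuleProfile]) -> pd.DataFrame:
    """Lifestyle-composition matrix (modules x lifestyles), fractions."""
    labels = sorted({l for p in profiles for l in p.lifestyle_composition})
    data = {
        f"module_{p.module_id}": [p.lifestyle_composition.get(l, 0.0) for l in labels]
        for p in profiles
    }
    return pd.DataFrame(data, index=labels).T
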