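"""Within-module connectivity (Zi), participation coefficient (Pi), role
classification and cross-stratum role-shift tables.

Zi is the z-score of a node's within-module degree, standardized over its
module (population sd; 0 when the sd is 0). Pi = 1 - sum_s (kappa_is/k_i)^2
over all modules s. Roles threshold at Zi = 2.5 and Pi = 0.62; values exactly
at a threshold fall to the peripheral side of that axis.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import CooccurrenceNetwork, CryonetError, TaxonomyTable
from .network_props import ModulePartition

Z_THRESHOLD = 2.5
P_THRESHOLD = 0.62

ROLE_LABELS = {
    "peripheral": "Peripheral",
    "connector": "Connectors",
    "module_hub": "Module hubs",
    "network_hub": "Network hubs",
}
GENERALIST_ROLES = ("connector", "module_hub", "network_hub")
ABSENT = "absent"


@dataclasses.dataclass
class ZiPiRecord:
    taxon_id: str
    module_id: int
    degree: int
    within_module_degree: int
    zi: float
    pi: float
    role: str


def classify_role(
    zi: float, pi: float, z_thresh: float = Z_THRESHOLD, p_thresh: float = P_THRESHOLD
) -> str:
    high_z = zi > z_thresh
    high_p = pi > p_thresh
    if high_z and high_p:
        return "network_hub"
    if high_z:
        return "module_hub"
    if high_p:
        return "connector"
    return "peripheral"


def zipi(
    net: CooccurrenceNetwork, partition: ModulePartition
) -> list[ZiPiRecord]:
    graph = net.graph
    missing = set(graph.nodes) - set(partition.assignment)
    if missing:
        raise CryonetError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    # kappa[node][module] = links from node into module
    kappa: dict[str, dict[int, int]] = {n: {} for n in graph.nodes}
    for u, v in graph.edges:
        mu, mv = partition.assignment[u], partition.assignment[v]
        kappa[u][mv] = kappa[u].get(mv, 0) + 1
        kappa[v][mu] = kappa[v].get(mu, 0) + 1
    own_kappa = {
        n: kappa[n].get(partition.assignment[n], 0) for n in graph.nodes
    }
    z_stats: dict[int, tuple[float, float]] = {}
    for module_id in set(partition.assignment.values()):
        ks = np.array(
            [own_kappa[n] for n in graph.nodes if partition.assignment[n] == module_id],
            dtype=float,
        )
        z_stats[module_id] = (float(ks.mean()), float(ks.std()))
    records = []
    for node in graph.nodes:
        k = graph.degree(node)
        module_id = partition.assignment[node]
        mean_k, sd_k = z_stats[module_id]
        zi_val = 0.0 if sd_k == 0 else (own_kappa[node] - mean_k) / sd_k
        pi_val = 1.0 - sum((c / k) ** 2 for c in kappa[node].values())
        records.append(
            ZiPiRecord(
                taxon_id=node,
                module_id=module_id,
                degree=int(k),
                within_module_degree=int(own_kappa[node]),
                zi=zi_val,
                pi=pi_val,
                role=classify_role(zi_val, pi_val),
            )
        )
    return records


def zipi_frame(records: Sequence[ZiPiRecord]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            (r.taxon_id, r.module_id, r.degree, r.within_module_degree, r.zi, r.pi, r.role)
            for r in records
        ],
        columns=["taxon", "module", "k", "kappa", "Zi", "Pi", "role"],
    )
    return frame.set_index("taxon")


def zipi_summary(records: Sequence[ZiPiRecord]) -> dict:
    """Counts the results sections report: generalists, % peripherals, and
    % of peripherals with no edge outside their own module (Pi = 0)."""
    n = len(records)
    peripherals = [r for r in records if r.role == "peripheral"]
    generalists = [r for r in records if r.role in GENERALIST_ROLES]
    pi_zero = [r for r in peripherals if r.pi == 0.0]
    return {
        "n_nodes": n,
        "n_generalists": len(generalists),
        "n_connectors": sum(r.role == "connector" for r in records),
        "n_module_hubs": sum(r.role == "module_hub" for r in records),
        "n_network_hubs": sum(r.role == "network_hub" for r in records),
        "pct_peripheral": 100.0 * len(peripherals) / n if n else float("nan"),
        "pct_peripheral_pi_zero": (
            100.0 * len(pi_zero) / len(peripherals) if peripherals else float("nan")
        ),
    }


def role_shift(
    records_by_stratum: Mapping[str, Sequence[ZiPiRecord]],
    taxonomy: TaxonomyTable | None = None,
    lifestyles: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Table of every taxon that is a generalist in at least one stratum.

    One row per taxon; one column per stratum holding the display role label
    or ``"absent"`` when the taxon is not a node in that stratum's network.
    """
    if len(records_by_stratum) < 2:
        raise CryonetError("role shift needs at least 2 strata")
    strata = list(records_by_stratum)
    role_of: dict[str, dict[str, str]] = {s: {} for s in strata}
    for stratum, records in records_by_stratum.items():
        for r in records:
            role_of[stratum][r.taxon_id] = r.role
    generalists = sorted(
        {
            r.taxon_id
            for records in records_by_stratum.values()
            for r in records
            if r.role in GENERALIST_ROLES
        }
    )
    rows = []
    for taxon in generalists:
        row: dict[str, str] = {"taxon": taxon}
        if taxonomy is not None:
            row["genus"] = taxonomy.genus(taxon)
            row["species"] = taxonomy.rank(taxon, "species")
        if lifestyles is not None:
            row["lifestyle"] = lifestyles.get(taxon, "unassigned")
        for stratum in strata:
            role = role_of[stratum].get(taxon)
            row[stratum] = ABSENT if role is None else ROLE_LABELS[role]
        rows.append(row)
    columns = ["taxon"]
    if taxonomy is not None:
        columns += ["genus", "species"]
    if lifestyles is not None:
        columns += ["lifestyle"]
    columns += strata
    frame = pd.DataFrame(rows, columns=columns)
    return frame.set_index("taxon")


def shared_unique_nodes(
    networks_by_stratum: Mapping[str, CooccurrenceNetwork | Sequence[str]],
) -> dict:
    """Exact shared/unique node counts for every stratum combination.

    Returns ``{"unique": {stratum: count}, "shared": {"A&B": count, ...}}``
    with shared counts for every combination of >= 2 strata (Venn semantics:
    nodes present in exactly that combination).
    """
    if len(networks_by_stratum) < 2:
        raise CryonetError("need at least 2 strata")
    sets = {
        s: set(net.nodes() if isinstance(net, CooccurrenceNetwork) else net)
        for s, net in networks_by_stratum.items()
    }
    strata = list(sets)
    out: dict = {"unique": {}, "shared": {}}
    for s in strata:
        others = set().union(*(sets[t] for t in strata if t != s))
        out["unique"][s] = len(sets[s] - others)
    for r in range(2, len(strata) + 1):
        for combo in combinations(strata, r):
            inside = set.intersection(*(sets[s] for s in combo))
            outside = set().union(
                *(sets[s] for s in strata if s not in combo), set()
            )
            exactly = inside - outside if len(combo) < len(strata) else inside
            out["shared"]["&".join(combo)] = len(exactly)
    return out
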