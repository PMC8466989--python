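"""Synthetic zOTU-table generator with planted module/keystone structure and
covarying environmental factors.

Latent model
------------
Each module m has a standard-normal factor per sample. Regular members load
``a = sqrt(r)`` on their factor so every within-module pair has latent Pearson
correlation r, where ``r = 2 sin(pi * rho_s / 6)`` converts the target
Spearman ``rho_s`` into the latent Pearson of the Gaussian copula (the
mapping is approximate in the reverse direction but exact for the rank
correlation of bivariate normals). A planted module hub loads 1.0 (it IS the
factor), elevating its within-module degree.

Planted connectors load equally on the first three module factors. A
connector correlated above the 0.6 edge threshold with members of three
mutually INDEPENDENT modules is impossible — the squared correlations would
exceed the unit variance budget — so when connectors are requested the
module factors are given a modest pairwise correlation ``rho_f`` through a
shared bridge. The connector-member correlation is then
``a * sqrt((1 + 2 rho_f) / 3)`` (~0.68 at the defaults) while member pairs
from different modules only reach ``a^2 * rho_f`` (~0.28), far below the
edge threshold, so the planted modules stay separable.

Counts are compositional: per sample, relative weights are the softmax of
``mu + z + overdispersion * noise`` and counts are multinomial at the
sequencing depth. Environmental factors respond linearly to their linked
module factor on a latent scale, then map monotonically onto natural units
(which preserves Spearman correlations).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import (
    ENV_FACTORS,
    CryonetError,
    SampleMetadata,
    TaxonomyTable,
    TraitsTable,
    ZOTUTable,
)

#: target latent connector-member correlation: comfortably above the 0.6
#: edge threshold so connector edges reach every module, without dragging
#: cross-module member pairs (a^2 * rho_f) over it.
_CONNECTOR_MEMBER_R = 0.69

#: cap on the pairwise module-factor correlation used to reach that target.
_FACTOR_RHO_MAX = 0.55


def _factor_rho(a: float, k: int) -> float:
    """Pairwise module-factor correlation giving connector-member latent
    correlation ~_CONNECTOR_MEMBER_R, i.e. a * sqrt((1 + (k-1) rho) / k)."""
    if a < 0.3:
        return _FACTOR_RHO_MAX
    need = (_CONNECTOR_MEMBER_R / a) ** 2  # (1 + (k-1) rho) / k
    rho = (need * k - 1.0) / (k - 1.0)
    return float(np.clip(rho, 0.2, _FACTOR_RHO_MAX))

#: genus -> (lifestyle, trophic mode) pool for invented taxonomy/traits
_GENUS_POOL = [
    ("Mortierella", "Soil_Saprotroph", "saprotroph"),
    ("Penicillium", "unspecified_Saprotroph", "saprotroph"),
    ("Russula", "Ectomycorrhizal", "symbiotroph"),
    ("Tetracladium", "Litter_Saprotroph", "saprotroph"),
    ("Cladophialophora", "Soil_Saprotroph", "saprotroph"),
    ("Cortinarius", "Ectomycorrhizal", "symbiotroph"),
    ("Phialocephala", "Root_Endophyte", "symbiotroph"),
    ("Lachnum", "Litter_Saprotroph", "saprotroph"),
    ("Verrucaria", "Lichenized", "symbiotroph"),
    ("Neobulgaria", "Wood_Saprotroph", "saprotroph"),
    ("Oidiodendron", "Soil_Saprotroph", "saprotroph"),
    ("Cadophora", "Litter_Saprotroph", "saprotroph"),
    ("Cenococcum", "Ectomycorrhizal", "symbiotroph"),
    ("Vishniacozyma", "Soil_Saprotroph", "saprotroph"),
    ("Exophiala", "Root_Endophyte", "pathotroph"),
]


@dataclasses.dataclass
class SimulationSpec:
    n_samples: int = 60
    n_taxa: int = 200
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (30, 30, 30)
    within_module_rho: float = 0.6
    n_connectors: int = 0
    n_module_hubs: int = 0
    background_taxa: int | None = None  # derived when None
    sequencing_depth: int = 50_000
    overdispersion: float = 0.15
    env_spec: Mapping[str, tuple[int | None, float]] = dataclasses.field(
        default_factory=dict
    )
    horizons: tuple[str, ...] = ("topsoil", "cryoOM")
    sites: tuple[int, ...] = (1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if len(self.module_sizes) != self.n_modules:
            raise CryonetError("module_sizes length must equal n_modules")
        if any(s < 2 for s in self.module_sizes):
            raise CryonetError("every module needs at least 2 taxa")
        planted = sum(self.module_sizes) + self.n_connectors
        if self.background_taxa is None:
            self.background_taxa = self.n_taxa - planted
        if planted + self.background_taxa != self.n_taxa:
            raise CryonetError(
                f"module_sizes + connectors + background ({planted + self.background_taxa}) "
                f"must equal n_taxa ({self.n_taxa})"
            )
        if self.background_taxa < 0:
            raise CryonetError("planted taxa exceed n_taxa")
        if not 0 <= self.within_module_rho < 1:
            raise CryonetError("within_module_rho must lie in [0, 1)")
        if self.sequencing_depth < 1000:
            raise CryonetError("sequencing_depth must be >= 1000")
        if self.n_module_hubs > self.n_modules:
            raise CryonetError("at most one planted hub per module")
        if self.n_connectors > 0 and self.n_modules < 3:
            raise CryonetError("planting connectors needs >= 3 modules")
        for factor, (module, _effect) in self.env_spec.items():
            if factor not in ENV_FACTORS:
                raise CryonetError(f"unknown env factor {factor!r}")
            if module is not None and not 1 <= module <= self.n_modules:
                raise CryonetError(f"env factor {factor!r} linked to bad module")


@dataclasses.dataclass
class SimulationTruth:
    module_of: dict[str, object]  # taxon -> 1-based module id or "background"
    role_of: dict[str, str]  # taxon -> peripheral | connector | module_hub
    env_links: dict[str, int | None]  # factor -> linked module or None

    def taxa_with_role(self, role: str) -> list[str]:
        return [t for t, r in self.role_of.items() if r == role]


def spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson giving Spearman ``rho_s`` under a Gaussian copula."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _env_to_natural(factor: str, raw: np.ndarray) -> np.ndarray:
    """Monotone map from the latent env scale onto plausible units."""
    if factor == "moisture":
        return np.clip(55.0 + 12.0 * raw, 2.0, 98.0)
    if factor == "pH":
        return np.clip(6.5 + 0.7 * raw, 3.5, 9.5)
    base = {
        "DOC": 6.0,
        "DN": 2.5,
        "Ctot": 2.5,
        "Ntot": -0.5,
        "CN": 3.0,
        "BG": 5.5,
        "CBH": 4.0,
        "LAP": 4.0,
        "NAG": 4.5,
    }[factor]
    return np.exp(base + 0.6 * raw)


def simulate_community(
    spec: SimulationSpec,
) -> tuple[ZOTUTable, SampleMetadata, TaxonomyTable, TraitsTable, SimulationTruth]:
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_samples, spec.n_taxa
    r = spearman_to_pearson(spec.within_module_rho)
    a = np.sqrt(r)

    factors = rng.standard_normal((spec.n_modules, n))
    if spec.n_connectors > 0:
        k = spec.n_modules
        rho_f = _factor_rho(a, k)
        b = np.sqrt(rho_f)
        bridge = rng.standard_normal(n)
        factors = np.sqrt(1.0 - b**2) * factors + b * bridge
        connector_core = factors.sum(axis=0) / np.sqrt(k * (1.0 + (k - 1) * rho_f))

    # Base log-abundances, drawn before the latent field so the closure
    # compensation below can use the expected weights. Planted taxa must
    # clear the 0.1% abundance filter, but the background carries most of
    # the reads.
    n_planted = sum(spec.module_sizes) + spec.n_connectors
    mu = np.concatenate(
        [
            rng.normal(0.7, 0.15, n_planted),
            rng.normal(0.8, 0.8, spec.background_taxa),
        ]
    )

    latent = np.empty((s, n))
    module_of: dict[str, object] = {}
    role_of: dict[str, str] = {}
    taxa = [f"zOTU{i + 1}" for i in range(s)]
    idx = 0
    for m, size in enumerate(spec.module_sizes):
        for j in range(size):
            taxon = taxa[idx]
            module_of[taxon] = m + 1
            if j == 0 and m < spec.n_module_hubs:
                latent[idx] = factors[m]  # loading 1.0: the hub IS the factor
                role_of[taxon] = "module_hub"
            else:
                noise = rng.standard_normal(n)
                latent[idx] = a * factors[m] + np.sqrt(1.0 - a**2) * noise
                role_of[taxon] = "peripheral"
            idx += 1
    for _ in range(spec.n_connectors):
        taxon = taxa[idx]
        module_of[taxon] = "background"
        role_of[taxon] = "connector"
        latent[idx] = 0.995 * connector_core + np.sqrt(1.0 - 0.995**2) * rng.standard_normal(n)
        idx += 1
    # Softmax closure subtracts the abundance-weighted mean of the latent
    # field from every taxon's observable signal, which would attenuate the
    # planted correlations (connectors, riding the factors' common mode, are
    # hit hardest). Cancel it to first order by anti-loading the background:
    # the background absorbs the planted signal's weighted mean, so the
    # per-sample weighted mean of all latents stays flat. The induced
    # background-member correlations are far below the edge threshold.
    weights_expected = np.exp(mu)
    planted_mean = (
        weights_expected[:n_planted, np.newaxis] * latent[:n_planted]
    ).sum(axis=0)
    if spec.background_taxa > 0:
        compensation = planted_mean / weights_expected[n_planted:].sum()
    else:
        compensation = np.zeros(n)
    for _ in range(spec.background_taxa):
        taxon = taxa[idx]
        module_of[taxon] = "background"
        role_of[taxon] = "peripheral"
        latent[idx] = rng.standard_normal(n) - compensation
        idx += 1

    logits = mu[:, np.newaxis] + latent
    if spec.overdispersion > 0:
        logits = logits + spec.overdispersion * rng.standard_normal((s, n))
    weights = np.exp(logits)
    probs = weights / weights.sum(axis=0, keepdims=True)
    counts = np.empty((s, n), dtype=np.int64)
    for j in range(n):
        counts[:, j] = rng.multinomial(spec.sequencing_depth, probs[:, j])

    sample_ids = [f"S{j + 1}" for j in range(n)]
    table = ZOTUTable(taxa, sample_ids, counts)

    # metadata: contiguous horizon blocks, sites cycling within each block
    horizons = [
        spec.horizons[min(j * len(spec.horizons) // n, len(spec.horizons) - 1)]
        for j in range(n)
    ]
    sites = [spec.sites[j % len(spec.sites)] for j in range(n)]
    env_links: dict[str, int | None] = {}
    env_data: dict[str, np.ndarray] = {}
    for factor in ENV_FACTORS:
        module, effect = spec.env_spec.get(factor, (None, 0.0))
        env_links[factor] = module
        if module is None:
            raw = rng.standard_normal(n)
        else:
            raw = effect * factors[module - 1] + 0.5 * rng.standard_normal(n)
        env_data[factor] = _env_to_natural(factor, raw)
    meta_frame = pd.DataFrame(
        {"horizon": horizons, "site": sites, **env_data}, index=sample_ids
    )
    meta = SampleMetadata(meta_frame)

    # invented taxonomy and traits, deterministic from the seed
    genus_idx = rng.integers(0, len(_GENUS_POOL), s)
    unidentified = rng.random(s) < 0.15
    lineages = {}
    for i, taxon in enumerate(taxa):
        if unidentified[i]:
            lineages[taxon] = ("Fungi",)
        else:
            genus = _GENUS_POOL[genus_idx[i]][0]
            lineages[taxon] = (
                "Fungi",
                "unidentified",
                "unidentified",
                "unidentified",
                "unidentified",
                genus,
                "unidentified",
            )
    taxonomy = TaxonomyTable(lineages)
    traits = TraitsTable({g: (l, t) for g, l, t in _GENUS_POOL})
    truth = SimulationTruth(module_of, role_of, env_links)
    return table, meta, taxonomy, traits, truth


def default_paper_like_spec() -> SimulationSpec:
    """A ~500-taxon, 5-module community whose inferred per-stratum networks
    are modular (Q > 0.4) with recoverable planted hubs and connectors.

    40 samples per stratum: with ~50k pairwise tests, the BH-adjusted
    p < 0.01 edge rule needs |rho| well above 0.6 at n = 30, which starves
    the network; n = 40 makes the rho threshold the binding constraint.
    """
    return SimulationSpec(
        n_samples=80,
        n_taxa=500,
        n_modules=5,
        module_sizes=(48, 46, 44, 42, 40),
        within_module_rho=0.6,
        n_connectors=3,
        n_module_hubs=5,
        sequencing_depth=50_000,
        overdispersion=0.15,
        env_spec={
            "moisture": (1, 1.0),
            "DOC": (2, 0.8),
            "pH": (3, 1.0),
            "Ntot": (4, 0.8),
            "NAG": (5, 0.8),
        },
        horizons=("topsoil", "cryoOM"),
        sites=(1, 2),
        seed=0,
    )


def truth_to_json(truth: SimulationTruth) -> dict:
    return {
        "module_of": truth.module_of,
        "role_of": truth.role_of,
        "env_links": truth.env_links,
    }
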