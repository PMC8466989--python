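"""End-to-end orchestration: (simulate|load) -> filter -> network -> props ->
null -> zipi -> roleshift -> envcorr, one network per group level, with a run
manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__, env_assoc, io_model, network_build, network_props, preprocess
from . import synthetic as synth
from . import zipi_keystone as zipi_mod
from .io_model import CryonetError

log = logging.getLogger(__name__)

STAGES = (
    "input",
    "filter",
    "network",
    "props",
    "null",
    "zipi",
    "roleshift",
    "envcorr",
)


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str
    seed: int
    inputs: dict | None = None  # paths: zotu, metadata, taxonomy, traits
    simulation: synth.SimulationSpec | None = None
    group_by: str = "horizon"
    filter_params: preprocess.FilterParams = dataclasses.field(
        default_factory=preprocess.FilterParams
    )
    thresholds: network_build.EdgeThresholds = dataclasses.field(
        default_factory=network_build.EdgeThresholds
    )
    null_reps: int = 100
    module_algorithm: str = "greedy"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise CryonetError("supply exactly one of input tables or a simulation spec")
        if self.group_by not in ("horizon", "site"):
            raise CryonetError("group_by must be 'horizon' or 'site'")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = raw.pop("simulation", None)
    if sim is not None:
        if "env_spec" in sim:
            sim["env_spec"] = {
                k: (v[0], float(v[1])) for k, v in sim["env_spec"].items()
            }
        for key in ("module_sizes", "horizons", "sites"):
            if key in sim:
                sim[key] = tuple(sim[key])
        sim = synth.SimulationSpec(**sim)
    filt = preprocess.FilterParams(**raw.pop("filter", {}))
    thr = network_build.EdgeThresholds(**raw.pop("network", {}))
    return PipelineConfig(
        out_dir=raw.pop("out_dir"),
        seed=int(raw.pop("seed")),
        inputs=raw.pop("inputs", None),
        simulation=sim,
        group_by=raw.pop("group_by", "horizon"),
        filter_params=filt,
        thresholds=thr,
        null_reps=int(raw.pop("null_reps", 100)),
        module_algorithm=raw.pop("module_algorithm", "greedy"),
    )


def _file_hashes(out_dir: Path) -> dict[str, str]:
    hashes = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            hashes[str(path.relative_to(out_dir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return hashes


def run_pipeline(config: PipelineConfig) -> dict:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "cryonet_version": __version__,
        "seed": config.seed,
        "group_by": config.group_by,
        "filter": dataclasses.asdict(config.filter_params),
        "thresholds": dataclasses.asdict(config.thresholds),
        "null_reps": config.null_reps,
        "module_algorithm": config.module_algorithm,
        "stages": [],
    }

    # ---- stage: input -----------------------------------------------------
    if config.simulation is not None:
        table, meta, taxonomy, traits, truth = synth.simulate_community(
            config.simulation
        )
        io_model.write_zotu_table(table, out_dir / "zotu_table.tsv")
        io_model.write_metadata(meta, out_dir / "metadata.tsv")
        io_model.write_taxonomy(taxonomy, out_dir / "taxonomy.tsv")
        io_model.write_traits(traits, out_dir / "traits.tsv")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(synth.truth_to_json(truth), fh, indent=1, sort_keys=True)
    else:
        table = io_model.read_zotu_table(
            config.inputs["zotu"], config.inputs.get("orientation", "taxa_rows")
        )
        meta = io_model.read_metadata(config.inputs["metadata"])
        taxonomy = io_model.read_taxonomy(config.inputs["taxonomy"])
        traits = io_model.read_traits(config.inputs["traits"])
    meta.require_samples(table.sample_ids)
    manifest["stages"].append({"stage": "input", "n_taxa": table.shape[0]})

    lifestyles = io_model.assign_lifestyles(table, taxonomy, traits)
    rel = preprocess.relative_abundance(table)
    levels = sorted(set(meta.frame[config.group_by]), key=str)

    per_group: dict = {}
    for level in levels:
        name = str(level)
        gdir = out_dir / f"{config.group_by}={name}"
        gdir.mkdir(exist_ok=True)
        samples = [s for s in meta.samples_in_group(config.group_by, level) if s in table.sample_ids]
        try:
            per_group[name] = _run_group(
                config, name, gdir, rel, samples, lifestyles, taxonomy
            )
        except CryonetError as exc:
            raise CryonetError(
                f"pipeline failed for {config.group_by}={name}: {exc}"
            ) from exc
    for stage in ("filter", "network", "props", "null", "zipi"):
        manifest["stages"].append(
            {
                "stage": stage,
                "groups": {name: g.get(stage) for name, g in per_group.items()},
            }
        )

    # ---- stage: roleshift -------------------------------------------------
    records_by_stratum = {
        name: g["records"] for name, g in per_group.items() if g["records"]
    }
    if len(records_by_stratum) >= 2:
        shifts = zipi_mod.role_shift(records_by_stratum, taxonomy, lifestyles)
        shifts.to_csv(out_dir / "roleshift.tsv", sep="\t")
        shared = zipi_mod.shared_unique_nodes(
            {name: g["nodes"] for name, g in per_group.items() if g["nodes"]}
        )
        with open(out_dir / "shared_nodes.json", "w") as fh:
            json.dump(shared, fh, indent=1, sort_keys=True)
        manifest["stages"].append({"stage": "roleshift", "n_rows": len(shifts)})
    else:
        manifest["stages"].append({"stage": "roleshift", "skipped": "fewer than 2 non-empty strata"})

    # ---- stage: envcorr ---------------------------------------------------
    env_stage = {}
    for name, g in per_group.items():
        if g.get("profiles") is None:
            continue
        series = {f"module_{p.module_id}": p.abundance for p in g["profiles"]}
        for rec in g["records"]:
            if rec.role in zipi_mod.GENERALIST_ROLES:
                series[rec.taxon_id] = g["rel"].to_frame().loc[rec.taxon_id]
        corr = env_assoc.env_correlate(series, meta)
        corr.to_csv(out_dir / f"{config.group_by}={name}" / "envcorr.tsv", sep="\t", index=False)
        env_stage[name] = {"n_rows": len(corr)}
    manifest["stages"].append({"stage": "envcorr", "groups": env_stage})

    manifest["output_hashes"] = _file_hashes(out_dir)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _run_group(config, name, gdir, rel, samples, lifestyles, taxonomy) -> dict:
    out: dict = {"records": [], "nodes": [], "profiles": None, "rel": None}
    if len(samples) < 5:
        raise CryonetError(f"group has fewer than 5 samples ({len(samples)})")
    filtered = preprocess.filter_taxa(rel, config.filter_params, samples)
    io_model.write_rel_abundance(filtered, gdir / "filtered.tsv")
    out["filter"] = {
        "taxa_before": rel.shape[0],
        "taxa_after": filtered.shape[0],
        "abundance_pct_retained": preprocess.abundance_retained(filtered),
    }
    out["rel"] = filtered
    if filtered.shape[0] < 2:
        out["network"] = {"n_nodes": 0, "n_edges": 0}
        return out

    corr = network_build.spearman_matrix(filtered)
    mean_abund = dict(zip(filtered.taxa_ids, filtered.values.mean(axis=1)))
    net = network_build.build_network(
        corr,
        config.thresholds,
        node_attrs={"abundance": mean_abund, "lifestyle": lifestyles},
    )
    pairs = network_build.significant_pairs(corr, config.thresholds)
    pairs.to_csv(gdir / "edges.tsv", sep="\t", index=False)
    pos, neg = (net.edge_signs() if net.n_edges else (0, 0))
    out["network"] = {"n_nodes": net.n_nodes, "n_edges": net.n_edges,
                      "n_pos_edges": pos, "n_neg_edges": neg}
    if net.n_edges == 0:
        log.warning("%s: empty network", name)
        return out
    io_model.write_network(net, gdir / "network.graphml", "graphml")
    out["nodes"] = net.nodes()

    partition = network_props.detect_modules(
        net, algorithm=config.module_algorithm, seed=config.seed
    )
    report = network_props.topology_report(
        net,
        partition,
        total_taxa_after_filter=filtered.shape[0],
        abundance_pct_retained=out["filter"]["abundance_pct_retained"],
    )
    with open(gdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    log.info("%s: %s", name, report.to_dict())
    out["props"] = {"n_modules": report.n_modules, "modularity": report.modularity}

    null = network_props.random_ensemble(
        net.n_nodes,
        net.n_edges,
        reps=config.null_reps,
        seed=config.seed,
        algorithm=config.module_algorithm,
    )
    with open(gdir / "null.json", "w") as fh:
        json.dump(null.to_dict(), fh, indent=1, sort_keys=True)
    out["null"] = {"apl_mean": null.apl_mean, "cc_mean": null.cc_mean,
                   "modularity_mean": null.modularity_mean}

    records = zipi_mod.zipi(net, partition)
    zipi_mod.zipi_frame(records).to_csv(gdir / "zipi.tsv", sep="\t")
    out["records"] = records
    out["zipi"] = zipi_mod.zipi_summary(records)

    out["profiles"] = env_assoc.module_profiles(
        net, partition, filtered, lifestyles, top_k=5
    )
    env_assoc.composition_frame(out["profiles"]).to_csv(
        gdir / "module_composition.tsv", sep="\t"
    )
    return out
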