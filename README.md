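# cryonet

Co-occurrence network analysis for soil fungal zOTU count tables:

* **preprocess** — relative-abundance normalization, prevalence (> 30%) /
  mean-abundance (≥ 0.1%) filtering per stratum, alpha diversity (Chao1,
  Shannon, Simpson evenness).
* **network_build** — all-pairs tie-aware Spearman correlation with
  t-approximation p-values, Benjamini–Hochberg FDR over the upper triangle,
  and edge thresholding (|rho| ≥ 0.6 and adjusted p < 0.01 by default; a
  `--raw-p` flag thresholds unadjusted p instead).
* **network_props** — topology report (APL over connected pairs, degree,
  closeness, betweenness, edge density, diameter, global transitivity,
  modules, modularity), greedy/Louvain module detection, and seeded uniform
  Erdős–Rényi G(n, m) null ensembles (mean ± sd of APL, CC, modularity).
* **zipi_keystone** — within-module connectivity (Zi), participation
  coefficient (Pi), four-way role classification at (2.5, 0.62), cross-stratum
  role-shift tables and shared/unique node counts.
* **env_assoc** — module lifestyle composition, per-sample module abundance
  profiles, and Spearman correlation of modules / keystone taxa against
  log-transformed environmental factors with `*` / `**` significance stars.
* **synthetic** — a zOTU-table generator with planted module, hub and
  connector structure plus covarying environmental factors, so the whole
  pipeline is testable without any external data.
* **cli / pipeline** — end-to-end orchestration with a YAML config, one
  network per stratum, and a reproducibility manifest (identical config +
  seed ⇒ byte-identical outputs).

## CLI

Each stage is a subcommand (`cryonet <cmd> --help` for options):

```sh
cryonet simulate --out sim/ --seed 1            # built-in paper-like spec
cryonet filter --in sim/zotu_table.tsv --meta sim/metadata.tsv \
        --group horizon=topsoil --out filtered.tsv
cryonet network --in filtered.tsv --out net.graphml --edges-out edges.tsv
cryonet props --net net.graphml --null-reps 1000 --seed 1 --out props.json
cryonet zipi --net net.graphml --out zipi.tsv
cryonet roleshift --inputs topsoil=a.tsv --inputs cryoOM=b.tsv --out shifts.tsv
cryonet envcorr --net net.graphml --rel filtered.tsv --meta sim/metadata.tsv \
        --out envcorr.tsv
```

Or run everything from a config:

```sh
cryonet run --config config.yaml
```

```yaml
# config.yaml
out_dir: out
seed: 1
group_by: horizon            # or site
null_reps: 1000
module_algorithm: greedy     # or louvain
filter: {prevalence_min: 0.30, mean_abund_min: 0.001}
network: {rho_min: 0.6, p_max: 0.01, use_adjusted_p: true}
simulation:                  # alternatively: inputs: {zotu: ..., metadata: ...,
  n_samples: 80              #   taxonomy: ..., traits: ...}
  n_taxa: 500
  n_modules: 5
  module_sizes: [48, 46, 44, 42, 40]
  within_module_rho: 0.6
  n_connectors: 3
  n_module_hubs: 5
  sequencing_depth: 50000
  env_spec: {moisture: [1, 1.0], pH: [3, 1.0]}
  horizons: [topsoil, cryoOM]
  sites: [1, 2]
  seed: 1
```

Outputs land under `out/{horizon=...}/` (filtered table, edge list, GraphML
network, topology + null-ensemble JSON, Zi-Pi table, module composition and
environment correlations) plus cross-stratum `roleshift.tsv`,
`shared_nodes.json` and `manifest.json`.

## Input formats

* zOTU table: TSV/CSV, one id column + header; taxa as rows by default
  (`orientation=samples_rows` for the transpose).
* metadata: TSV indexed by sample id with `horizon`
  (topsoil/cryoOM/subsoil/permafrost), `site` (1–4) and the environmental
  factors `moisture, pH, DOC, DN, Ctot, Ntot, CN, BG, CBH, LAP, NAG`
  (missing values allowed, pairwise-deleted).
* taxonomy: `taxon_id <TAB> lineage`, semicolon-delimited ranks with or
  without `k__` prefixes.
* traits: `genus <TAB> lifestyle <TAB> trophic_mode`; genera absent from the
  table map to `unassigned`.
* networks: GraphML (full attributes) or edge TSV.
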