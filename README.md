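# zooregion

Zoogeographic analysis of binary species × geographic-unit incidence
matrices: hierarchical bioregionalisation, centres and areas of endemism,
biotic element analysis and per-unit endemism surfaces.

The package covers the full chain used in incidence-based regionalisation
studies of faunas recorded in *operational geographic units* (OGUs):

| Stage | Module | What it does |
|---|---|---|
| Data model & I/O | `zooregion.incidence` | species/OGU registries, adjacency graph, incidence CSV/TSV, fine-grid (QDS) presence scoring, declarative taxon ledger (exclude / synonymise / merge complex), matrix pruning |
| Similarity & clustering | `zooregion.similarity` | Jaccard similarity between OGU assemblages, UPGMA dendrogram (deterministic tie-breaking), cophenetic distances, Newick export |
| Regionalisation | `zooregion.regions` | phenon-line cuts into dominions … districts, contiguity enforcement on the adjacency graph, dissolution of orphan OGUs into the nearest/most-similar region |
| Centres of endemism | `zooregion.centres` | endemic/near-endemic classification per region, COEs (≥4 endemics) and CONEs (≥2 narrow endemics), characteristic vs narrow endemic labelling |
| PAE | `zooregion.pae` | parsimony analysis of endemicity: matrix preparation with an all-absent root, Fitch length, random-addition + TBR heuristic search, strict consensus, AOE extraction, NEXUS export |
| BEA | `zooregion.bea` | Kulczynski/Jaccard range distances, distratio clustering statistic, connected-range null model with Monte-Carlo test, nonmetric MDS, Gaussian-mixture-with-noise biotic elements, element shading maps |
| Endemism surfaces | `zooregion.metrics` | richness, dominion endemism, narrow endemism, weighted endemism (WE), richness-corrected WE, min-max normalisation, Fisher–Jenks natural-breaks classes |
| Synthetic data | `zooregion.synthetic` | lattice OGU systems with planted contiguous regions, vicariant species pools, leakage/noise/singleton controls, truth labels |
| Orchestration | `zooregion.pipeline`, `zooregion.cli` | one-config pipeline producing a full report bundle with a checksummed manifest |

## Tests

```bash
python -m pytest -q tests/
```

Unit tests per module plus property tests (hypothesis) and
`tests/test_acceptance.py`, which checks the documented acceptance
criteria: exact reproduction of the packaged regional-endemism fixture
totals, the taxon-ledger count, the narrow-endemic classification, UPGMA
against a naive average-linkage oracle, heuristic parsimony against
exhaustive enumeration, WE conservation, Jenks against an exhaustive
partition oracle, type-I calibration and power of the clustering test,
and perfect recovery of planted regions. Two acceptance tests require the
source study's supplementary incidence matrix, which is not
redistributable here; they fail with an explanatory message unless a
transcription is supplied at `data/s1_incidence.csv` (+
`data/s1_adjacency.csv`).

## CLI

```bash
# generate a synthetic system with planted regions
zooregion simulate --preset vicariant_clean --seed 1 --outdir sim/

# individual stages
zooregion cluster     --incidence sim/incidence.csv --out dendrogram.nwk
zooregion regionalise --incidence sim/incidence.csv --adjacency sim/adjacency.csv \
                      --thresholds province=0.05,district=0.2 --out hierarchy.tsv
zooregion centres     --incidence sim/incidence.csv --adjacency sim/adjacency.csv --out centres.tsv
zooregion pae         --incidence sim/incidence.csv --adjacency sim/adjacency.csv --outdir pae/
zooregion bea         --incidence sim/incidence.csv --adjacency sim/adjacency.csv --outdir bea/
zooregion metrics     --incidence sim/incidence.csv --outdir metrics/

# everything from one YAML config
zooregion pipeline --config config.yaml --outdir out/
```

The pipeline output directory contains: `incidence.csv`, `similarity.csv`,
`dendrogram.nwk`, `hierarchy.tsv`, `endemism_summary.tsv`, `centres.tsv`,
`pae_matrix.nex`, `pae_consensus.nwk`, `aoes.tsv`, `bea_test.json`,
`nmds_coords.csv`, `biotic_elements.tsv`, five `metric_*.tsv` surfaces and
a `manifest.json` with seeds and SHA-256 checksums of every artifact.

A minimal `config.yaml`:

```yaml
incidence_path: sim/incidence.csv
adjacency_path: sim/adjacency.csv
phenon_scheme: [[province, 0.05], [district, 0.2]]
pae_replicates: 5
bea_n_sim: 200
bea_seed: 0
```

## Packaged fixtures

- `zooregion/fixtures/table2_status.tsv` — 73 species × 5 regions of
  endemic-status marks, with the per-region species-present totals as
  metadata;
- `zooregion/fixtures/table3_centres.tsv` — 29 centre-restricted species
  with range descriptors and overrides for the characteristic/narrow
  classifier;
- `zooregion/fixtures/taxon_ledger.yaml` — the 79-name original registry
  and the declarative ledger rules reducing it to 73 analysis taxa.
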