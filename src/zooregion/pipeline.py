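"""One-config orchestration of the full analysis chain.

``run_pipeline`` takes a validated :class:`PipelineConfig` and produces,
in one output directory: similarity CSV, dendrogram Newick, hierarchy
TSV, endemism summary TSV, centres TSV, PAE NEXUS + consensus Newick +
AOE TSV, BEA JSON + element TSV + NMDS CSV, metric TSVs and a manifest
with seeds and input checksums.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from zooregion import bea, centres, metrics, pae, regions, similarity
from zooregion.incidence import AdjacencyGraph, IncidenceMatrix, read_incidence, write_incidence

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    incidence_path: str | None = None
    adjacency_path: str | None = None
    phenon_scheme: list = field(
        default_factory=lambda: [["province", 0.05], ["district", 0.15]]
    )
    coe_min_endemics: int = 4
    cone_min_narrow: int = 2
    cone_max_extent: int = 3
    pae_replicates: int = 5
    pae_max_trees: int = 1000
    pae_seed: int = 0
    bea_metric: str = "kulczynski"
    bea_prop: float = 0.25
    bea_n_sim: int = 200
    bea_seed: int = 0
    bea_dims: int = 2
    bea_max_k: int = 10
    bea_neighbor_cap: int | None = None
    metrics_k_classes: int = 5
    dominion: list | None = None  # OGU ids of the dominion; None = all
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Cross-field checks; returns a list of human-readable errors."""
    errors = []
    thresholds = [t for _, t in config.phenon_scheme]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        errors.append("phenon thresholds must be strictly increasing")
    if any(not 0 <= t <= 1 for t in thresholds):
        errors.append("phenon thresholds must lie in [0, 1]")
    if not 0 < config.bea_prop <= 0.5:
        errors.append("bea_prop must lie in (0, 0.5]")
    if config.bea_metric not in bea.METRICS:
        errors.append(f"bea_metric must be one of {bea.METRICS}")
    if config.coe_min_endemics < 1:
        errors.append("coe_min_endemics must be positive")
    if config.cone_min_narrow < 1:
        errors.append("cone_min_narrow must be positive")
    if config.pae_replicates < 1:
        errors.append("pae_replicates must be positive")
    if config.bea_n_sim < 1:
        errors.append("bea_n_sim must be positive")
    if config.bea_dims < 1:
        errors.append("bea_dims must be positive")
    if config.metrics_k_classes < 1 or config.metrics_k_classes > 5:
        errors.append("metrics_k_classes must lie in 1..5")
    return errors


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir,
    m: IncidenceMatrix | None = None,
    g: AdjacencyGraph | None = None,
) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timers: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise StageError(name, exc) from exc
            timers[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.2fs", name, timers[name])

        return deco

    state: dict = {}

    @stage("load")
    def _load():
        state["m"] = m if m is not None else read_incidence(config.incidence_path)
        if g is not None:
            state["g"] = g
        else:
            state["g"] = AdjacencyGraph.read_edge_list(
                config.adjacency_path, nodes=state["m"].ogu_ids
            )
        if config.bea_neighbor_cap:
            state["g_bea"] = state["g"].cap_neighbors(config.bea_neighbor_cap)
        else:
            state["g_bea"] = state["g"]
        p = outdir / "incidence.csv"
        write_incidence(state["m"], p)
        artifacts["incidence"] = p.name

    @stage("similarity")
    def _similarity():
        state["s"] = similarity.jaccard_similarity(state["m"])
        p = outdir / "similarity.csv"
        state["s"].write_csv(p)
        artifacts["similarity"] = p.name
        state["d"] = similarity.upgma(state["s"])
        p = outdir / "dendrogram.nwk"
        p.write_text(state["d"].to_newick() + "\n", encoding="utf-8")
        artifacts["dendrogram"] = p.name

    @stage("regionalisation")
    def _regionalise():
        scheme = regions.PhenonScheme([(n, t) for n, t in config.phenon_scheme])
        state["hierarchy"] = regions.build_hierarchy(
            state["d"], scheme, state["g"], state["s"], state["m"]
        )
        p = outdir / "hierarchy.tsv"
        state["hierarchy"].write_tsv(p)
        artifacts["hierarchy"] = p.name

    @stage("centres")
    def _centres():
        h = state["hierarchy"]
        deepest = h.levels[-1]
        coes = centres.identify_coes(
            h, state["m"], min_endemics=config.coe_min_endemics, level=deepest
        )
        district_threshold = dict(
            (n, t) for n, t in config.phenon_scheme
        ).get(deepest, config.phenon_scheme[-1][1])
        flags = metrics.narrow_endemism_flags(state["m"], coes, config.overrides)
        cones = centres.identify_cones(
            state["d"],
            state["m"],
            {s: f.flagged for s, f in flags.items()},
            district_threshold,
            min_narrow=config.cone_min_narrow,
            max_extent=config.cone_max_extent,
        )
        cs = centres.CentreSet(coes.centres + cones.centres)
        for c in cs.centres:
            if c.kind == "COE":
                areas = {o.ogu_id: o.area for o in state["m"].ogus}
                if any(v is None for v in areas.values()):
                    areas = None
                c.labels = centres.classify_characteristic_narrow(
                    c, state["m"], areas=areas, cones=cones,
                    overrides=config.overrides,
                )
        state["centres"] = cs
        state["narrow_flags"] = metrics.narrow_endemism_flags(
            state["m"], cs, config.overrides
        )
        p = outdir / "centres.tsv"
        cs.write_tsv(p)
        artifacts["centres"] = p.name
        regions_named = {
            r.name: set(r.all_members)
            for level in h.levels
            for r in h.at_level(level)
        }
        summary = centres.summarise_endemism(state["m"], regions_named)
        p = outdir / "endemism_summary.tsv"
        summary.to_csv(p, sep="\t")
        artifacts["endemism_summary"] = p.name

    @stage("pae")
    def _pae():
        pm, report = pae.prepare_pae_matrix(state["m"])
        p = outdir / "pae_matrix.nex"
        p.write_text(pm.to_nexus(), encoding="utf-8")
        artifacts["pae_matrix"] = p.name
        result = pae.heuristic_search(
            pm,
            n_replicates=config.pae_replicates,
            seed=config.pae_seed,
            max_trees=config.pae_max_trees,
        )
        consensus = pae.strict_consensus(result.trees)
        p = outdir / "pae_consensus.nwk"
        p.write_text(pae.consensus_to_newick(consensus, pm.taxa) + "\n", encoding="utf-8")
        artifacts["pae_consensus"] = p.name
        aoes = pae.extract_aoes(
            consensus, pm.taxa, state["m"], state["g"], report.singleton_species
        )
        state["aoes"] = aoes
        p = outdir / "aoes.tsv"
        pae.write_aoe_tsv(aoes, p)
        artifacts["aoes"] = p.name

    @stage("bea")
    def _bea():
        test = bea.clustering_test(
            state["m"],
            state["g_bea"],
            n_sim=config.bea_n_sim,
            seed=config.bea_seed,
            prop=config.bea_prop,
            metric=config.bea_metric,
        )
        p = outdir / "bea_test.json"
        p.write_text(test.to_json() + "\n", encoding="utf-8")
        artifacts["bea_test"] = p.name
        d = bea.range_distance(state["m"], config.bea_metric)
        emb = bea.nmds(d, dims=config.bea_dims, seed=config.bea_seed)
        p = outdir / "nmds_coords.csv"
        with open(p, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["species"] + [f"dim{i+1}" for i in range(config.bea_dims)])
            for sid, xy in zip(d.species_ids, emb.coords):
                w.writerow([sid] + [f"{v:.6g}" for v in xy])
        artifacts["nmds_coords"] = p.name
        elements = bea.cluster_elements(
            emb.coords, max_k=config.bea_max_k, seed=config.bea_seed,
            species_ids=d.species_ids,
        )
        state["elements"] = elements
        p = outdir / "biotic_elements.tsv"
        elements.write_tsv(p)
        artifacts["biotic_elements"] = p.name

    @stage("metrics")
    def _metrics():
        msurf = state["m"]
        dominion = config.dominion or list(msurf.ogu_ids)
        rich = metrics.species_richness(msurf)
        dom = metrics.dominion_endemism(msurf, dominion)
        narrow = metrics.narrow_endemism(msurf, state["narrow_flags"])
        we = metrics.weighted_endemism(msurf)
        cwe = metrics.corrected_weighted_endemism(we, rich)
        for surf in (rich, dom, narrow, we, cwe):
            p = outdir / f"metric_{surf.metric_name}.tsv"
            surf.write_tsv(p, k=config.metrics_k_classes)
            artifacts[f"metric_{surf.metric_name}"] = p.name

    manifest = {
        "artifacts": artifacts,
        "checksums": {k: _sha256(outdir / v) for k, v in artifacts.items()},
        "seeds": {
            "pae_seed": config.pae_seed,
            "bea_seed": config.bea_seed,
        },
        "timers_s": timers,
        "config": {k: v for k, v in config.__dict__.items()},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
    )
    return manifest
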