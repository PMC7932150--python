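"""Synthetic OGU systems and incidence matrices with planted structure.

Scenarios generate a connected planar adjacency (a rectangular lattice),
partition it into contiguous "true" regions, and grow species ranges as
connected sets inside a home region, with optional presence leakage,
region-free noise species and planted single-OGU endemics.  Truth labels
(home region per species, planted region per OGU) ride along so recovery
can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from zooregion.incidence import OGU, AdjacencyGraph, IncidenceMatrix, SpeciesRecord


@dataclass
class SyntheticScenario:
    n_ogus: int = 40
    lattice_shape: tuple = (5, 8)
    k_regions: int = 4
    n_species: int = 73
    range_size_p: float = 0.35  # geometric law parameter
    leakage: float = 0.0
    p_noise: float = 0.0
    n_singletons: int = 0
    singleton_ogus: tuple = ()
    area_sigma: float = 0.6  # lognormal spread of OGU areas
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.lattice_shape
        if rows * cols != self.n_ogus:
            raise ValueError("lattice shape must cover n_ogus exactly")
        for p in (self.leakage, self.p_noise):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < self.range_size_p < 1:
            raise ValueError("range_size_p must lie in (0, 1)")
        if self.k_regions < 1 or self.k_regions > self.n_ogus:
            raise ValueError("k_regions out of range")


PRESETS = {
    # clean vicariance with ranges large enough for the clustering test to
    # have power at moderate simulation counts
    "vicariant_clean": SyntheticScenario(
        leakage=0.0, p_noise=0.0, n_singletons=6, range_size_p=0.10
    ),
    "vicariant_leaky": SyntheticScenario(
        leakage=0.05, p_noise=0.1, n_singletons=6, range_size_p=0.10
    ),
    "null_random": SyntheticScenario(k_regions=1, p_noise=1.0),
    # narrow-endemism skew (median range <= 4 OGUs) like the motivating data
    "paperlike40x73": SyntheticScenario(
        k_regions=4, leakage=0.05, p_noise=0.1, n_singletons=6
    ),
}


def scenario(name: str, **overrides) -> SyntheticScenario:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    base = PRESETS[name]
    return SyntheticScenario(**{**base.__dict__, **overrides})


@dataclass
class TruthLabels:
    region_of_ogu: dict = field(default_factory=dict)  # ogu -> region index
    home_region: dict = field(default_factory=dict)  # species -> region index | "noise"
    kind: dict = field(default_factory=dict)  # species -> regional|noise|singleton

    def write_tsv(self, path):
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["record", "id", "label"])
            for o, r in sorted(self.region_of_ogu.items()):
                w.writerow(["ogu", o, r])
            for s in sorted(self.home_region):
                w.writerow(["species", s, f"{self.home_region[s]}:{self.kind[s]}"])


def generate_ogus(spec: SyntheticScenario) -> tuple[list[OGU], AdjacencyGraph, TruthLabels]:
    """Lattice OGU system with lognormal areas and planted contiguous regions.

    Regions are vertical bands of lattice columns, guaranteeing both
    contiguity and a partition of the OGUs.
    """
    if spec.n_ogus < 4:
        raise ValueError("need at least 4 OGUs")
    rows, cols = spec.lattice_shape
    rng = np.random.default_rng(spec.seed)
    grid = nx.grid_2d_graph(rows, cols)

    def ogu_id(rc):
        r, c = rc
        return f"O{r * cols + c + 1:02d}"

    ids = {rc: ogu_id(rc) for rc in grid.nodes}
    areas = rng.lognormal(mean=0.0, sigma=spec.area_sigma, size=spec.n_ogus)
    ogus = [
        OGU(ids[(r, c)], name=f"unit r{r}c{c}", area=float(areas[r * cols + c]))
        for r in range(rows)
        for c in range(cols)
    ]
    edges = [(ids[a], ids[b]) for a, b in grid.edges]
    g = AdjacencyGraph([o.ogu_id for o in ogus], edges)

    # contiguous vertical bands of columns
    band = np.array_split(np.arange(cols), spec.k_regions)
    col_region = {}
    for ri, colset in enumerate(band):
        for c in colset:
            col_region[c] = ri
    truth = TruthLabels()
    for r in range(rows):
        for c in range(cols):
            truth.region_of_ogu[ids[(r, c)]] = col_region[c]
    return ogus, g, truth


def _grow_in_subgraph(g: AdjacencyGraph, allowed: set, size: int, rng) -> set:
    nodes = sorted(allowed)
    start = nodes[rng.integers(len(nodes))]
    chosen = {start}
    frontier = (g.neighbors(start) & allowed) - chosen
    while len(chosen) < size and frontier:
        pick = sorted(frontier)[rng.integers(len(frontier))]
        chosen.add(pick)
        frontier |= g.neighbors(pick) & allowed
        frontier -= chosen
    return chosen


def generate_species(
    spec: SyntheticScenario,
) -> tuple[IncidenceMatrix, AdjacencyGraph, TruthLabels]:
    """Incidence matrix with planted regional species pools.

    Each non-noise species grows a connected range inside its home region
    (size drawn geometric, clipped to the region); every presence other
    than the seed OGU relocates outside the home region with probability
    ``leakage``.  Noise species grow region-free connected ranges.
    Singletons occupy exactly one designated OGU.
    """
    ogus, g, truth = generate_ogus(spec)
    rng = np.random.default_rng(spec.seed + 1)
    ogu_ids = [o.ogu_id for o in ogus]
    col_index = {o: j for j, o in enumerate(ogu_ids)}
    region_members = {}
    for o, r in truth.region_of_ogu.items():
        region_members.setdefault(r, set()).add(o)

    n_regular = spec.n_species - spec.n_singletons
    if n_regular < 0:
        raise ValueError("n_singletons exceeds n_species")
    species = []
    cells = np.zeros((spec.n_species, spec.n_ogus), dtype=np.int8)
    outside_pool = {r: sorted(set(ogu_ids) - region_members[r]) for r in region_members}

    for i in range(n_regular):
        sid = f"sp{i + 1:03d}"
        is_noise = rng.random() < spec.p_noise
        size = int(min(rng.geometric(spec.range_size_p), spec.n_ogus))
        if is_noise:
            rng_set = _grow_in_subgraph(g, set(ogu_ids), size, rng)
            truth.home_region[sid] = "noise"
            truth.kind[sid] = "noise"
        else:
            home = int(rng.integers(spec.k_regions))
            members = region_members[home]
            size = min(size, len(members))  # clip to region, logged via truth
            rng_set = _grow_in_subgraph(g, members, size, rng)
            if spec.leakage > 0 and len(rng_set) > 1 and outside_pool[home]:
                moved = set()
                kept = set()
                seed_ogu = sorted(rng_set)[0]
                for o in sorted(rng_set):
                    if o != seed_ogu and rng.random() < spec.leakage:
                        moved.add(o)
                    else:
                        kept.add(o)
                for _ in moved:
                    kept.add(outside_pool[home][rng.integers(len(outside_pool[home]))])
                rng_set = kept
            truth.home_region[sid] = home
            truth.kind[sid] = "regional"
        for o in rng_set:
            cells[i, col_index[o]] = 1
        species.append(SpeciesRecord(sid))

    # planted single-OGU endemics, cycling through designated OGUs
    designated = list(spec.singleton_ogus)
    if not designated and spec.n_singletons:
        # default: one OGU per region, first few regions
        designated = [sorted(region_members[r])[0] for r in sorted(region_members)][:3]
    for j in range(spec.n_singletons):
        sid = f"end{j + 1:03d}"
        ogu = designated[j % len(designated)]
        cells[n_regular + j, col_index[ogu]] = 1
        species.append(SpeciesRecord(sid))
        truth.home_region[sid] = truth.region_of_ogu[ogu]
        truth.kind[sid] = "singleton"

    return IncidenceMatrix(species, ogus, cells), g, truth
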