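"""Phenon-line regionalisation of a UPGMA dendrogram.

A :class:`PhenonScheme` places similarity thresholds at named hierarchy
levels (dominion .. district).  Each level's cut is forced to be
geographically contiguous on the adjacency graph; OGUs stranded outside a
contiguous core are *dissolved* into the geographically nearest (graph
adjacency, hop distance as fallback) and ecologically closest (highest
mean Jaccard similarity) core.  Dissolved members are recorded separately
and never count as clustering evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from zooregion.incidence import AdjacencyGraph, IncidenceMatrix
from zooregion.similarity import Dendrogram, SimilarityMatrix

LEVEL_NAMES = ("dominion", "subdominion", "province", "subprovince", "district")


@dataclass
class PhenonScheme:
    """Ordered (level_name, similarity_threshold) pairs, thresholds strictly increasing."""

    levels: list[tuple[str, float]]

    def __post_init__(self):
        thresholds = [t for _, t in self.levels]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("phenon thresholds must be strictly increasing with level depth")
        for name, t in self.levels:
            if not 0 <= t <= 1:
                raise ValueError(f"threshold {t} for level {name!r} outside [0, 1]")

    @property
    def names(self):
        return [n for n, _ in self.levels]


@dataclass
class Region:
    name: str
    level: str
    members: frozenset  # contiguous core
    dissolved_members: frozenset = frozenset()
    parent: str | None = None

    @property
    def all_members(self) -> frozenset:
        return self.members | self.dissolved_members


@dataclass
class RegionHierarchy:
    """Per-level named partitions with parent links."""

    levels: list[str]
    regions: dict[str, list[Region]] = field(default_factory=dict)

    def at_level(self, level: str) -> list[Region]:
        return self.regions.get(level, [])

    def region_of(self, level: str, ogu_id: str) -> Region | None:
        for r in self.at_level(level):
            if ogu_id in r.all_members:
                return r
        return None

    def to_rows(self):
        rows = []
        for level in self.levels:
            for r in self.at_level(level):
                rows.append(
                    {
                        "level": level,
                        "region": r.name,
                        "parent": r.parent or "",
                        "members": " ".join(sorted(r.members)),
                        "dissolved_members": " ".join(sorted(r.dissolved_members)),
                    }
                )
        return rows

    def write_tsv(self, path):
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(
                fh,
                ["level", "region", "parent", "members", "dissolved_members"],
                delimiter="\t",
            )
            w.writeheader()
            w.writerows(self.to_rows())


def cut_phenon(d: Dendrogram, threshold: float) -> list[frozenset]:
    """Clusters = maximal subtrees whose merge similarity (1 - height) >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return d.clusters_at(1.0 - threshold)


def enforce_contiguity(
    partition, g: AdjacencyGraph, m: IncidenceMatrix | None = None
) -> tuple[list[frozenset], set]:
    """Split each cluster into connected components; keep the largest as core.

    Ties on component size break by total species presences (when a
    matrix is supplied), then by lexicographically smallest member label.
    All non-core components become orphans.
    """
    cores: list[frozenset] = []
    orphans: set = set()
    for cluster in partition:
        for o in cluster:
            if not g.has_node(o):
                raise ValueError(f"OGU {o!r} missing from adjacency graph")
        comps = g.connected_components(cluster)
        if len(comps) == 1:
            cores.append(frozenset(cluster))
            continue

        def species_count(comp):
            if m is None:
                return 0
            return sum(len(m.assemblage(o)) for o in comp)

        ranked = sorted(
            comps, key=lambda c: (-len(c), -species_count(c), sorted(c))
        )
        cores.append(frozenset(ranked[0]))
        for comp in ranked[1:]:
            orphans.update(comp)
    return cores, orphans


def dissolve_orphans(
    orphans, cores, g: AdjacencyGraph, s: SimilarityMatrix
) -> dict[str, int]:
    """Assign each orphan OGU to a core; returns orphan -> core index.

    Geographic nearness first: among cores with a graph neighbour of the
    orphan (counting already-dissolved orphans as part of their core), the
    ecologically closest wins -- highest mean Jaccard similarity between
    the orphan and the core's *original* members.  Orphans with no
    adjacent core are deferred until a dissolved neighbour links them;
    an orphan with no graph path to any core is an error.
    """
    cores = [frozenset(c) for c in cores]
    grown = [set(c) for c in cores]  # cores plus absorbed orphans, for adjacency
    assignment: dict[str, int] = {}
    pending = set(orphans)
    while pending:
        placed = None
        # deterministic scan order
        for o in sorted(pending):
            adjacent = [
                i for i, gset in enumerate(grown) if g.neighbors(o) & gset
            ]
            if not adjacent:
                continue
            best = max(
                adjacent,
                key=lambda i: (s.mean_similarity(o, sorted(cores[i])), -i),
            )
            placed = (o, best)
            break
        if placed is None:
            raise ValueError(
                f"orphan OGU(s) {sorted(pending)} have no graph path to any core"
            )
        o, i = placed
        assignment[o] = i
        grown[i].add(o)
        pending.discard(o)
    return assignment


def build_hierarchy(
    d: Dendrogram,
    scheme: PhenonScheme,
    g: AdjacencyGraph,
    s: SimilarityMatrix,
    m: IncidenceMatrix | None = None,
    names: dict | None = None,
) -> RegionHierarchy:
    """Apply cut -> contiguity -> dissolution per level, nesting top-down.

    Lower-level cuts are computed within each parent region (its core plus
    dissolved members), so every level refines the one above.  Region
    names come from ``names`` (map level -> {frozenset(core): name}) or
    are auto-generated.
    """
    hierarchy = RegionHierarchy(levels=list(scheme.names))
    parent_regions: list[Region] | None = None
    for level, threshold in scheme.levels:
        raw = cut_phenon(d, threshold)
        level_regions: list[Region] = []
        scopes = (
            [(None, frozenset(d.leaves))]
            if parent_regions is None
            else [(r, r.all_members) for r in parent_regions]
        )
        counter = 1
        for parent, scope in scopes:
            # refine: intersect the level's global cut with the parent scope
            clusters = [c & scope for c in raw]
            clusters = [c for c in clusters if c]
            cores, orphans = enforce_contiguity(clusters, g, m)
            assignment = dissolve_orphans(orphans, cores, g, s) if orphans else {}
            dissolved_by_core: dict[int, set] = {}
            for o, i in assignment.items():
                dissolved_by_core.setdefault(i, set()).add(o)
            for i, core in enumerate(cores):
                name = None
                if names and level in names:
                    name = names[level].get(core)
                if name is None:
                    name = f"{level}_{counter}"
                counter += 1
                level_regions.append(
                    Region(
                        name=name,
                        level=level,
                        members=core,
                        dissolved_members=frozenset(dissolved_by_core.get(i, set())),
                        parent=parent.name if parent else None,
                    )
                )
        hierarchy.regions[level] = level_regions
        parent_regions = level_regions
    return hierarchy


def propose_thresholds(d: Dendrogram, n_levels: int) -> list[float]:
    """Suggest phenon similarity thresholds at the largest height gaps.

    Sorts merge heights, finds the ``n_levels`` widest gaps between
    consecutive distinct heights and returns the similarity midpoints in
    increasing order.  A helper for exploratory use; schemes remain
    explicit config.
    """
    heights = sorted({m.height for m in d.merges})
    if len(heights) < 2:
        return [0.5] * n_levels
    gaps = [
        (heights[i + 1] - heights[i], (heights[i] + heights[i + 1]) / 2)
        for i in range(len(heights) - 1)
    ]
    gaps.sort(key=lambda x: (-x[0], x[1]))
    cuts = sorted(mid for _, mid in gaps[:n_levels])
    # similarity thresholds increase with level depth; deduplicate defensively
    out = []
    for c in reversed(cuts):
        t = 1.0 - c
        while out and t <= out[-1]:
            t = out[-1] + 1e-6
        out.append(t)
    return out
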