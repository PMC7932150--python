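"""Data model and I/O for species, OGUs, adjacency and incidence matrices.

An :class:`IncidenceMatrix` is a binary species x OGU presence/absence
table with attached species and OGU registries.  This module also houses
the fine-grid (QDS) presence-scoring rules, the declarative taxon ledger
(exclusions, synonymies, species-complex merges) and matrix pruning.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: status flags a species record may carry
STATUS_FLAGS = frozenset(
    {"merged_complex", "synonymised", "excluded", "override_narrow", "override_not_narrow"}
)

TRUTHY_TOKENS = frozenset({"1", "1.0", "true", "yes"})
FALSY_TOKENS = frozenset({"0", "0.0", "false", "no", ""})


@dataclass(frozen=True)
class SpeciesRecord:
    """One analysis taxon (species or merged species complex)."""

    species_id: str
    name: str = ""
    genus: str = ""
    family: str = ""
    status_flags: frozenset = frozenset()

    def __post_init__(self):
        unknown = set(self.status_flags) - STATUS_FLAGS
        if unknown:
            raise ValueError(f"unknown status flags {sorted(unknown)} on {self.species_id!r}")


@dataclass(frozen=True)
class OGU:
    """One operational geographic unit."""

    ogu_id: str
    name: str = ""
    area: float | None = None
    n_qds: int | None = None

    def __post_init__(self):
        if self.area is not None and self.area < 0:
            raise ValueError(f"negative area for OGU {self.ogu_id!r}")
        if self.n_qds is not None and self.n_qds <= 0:
            raise ValueError(f"non-positive n_qds for OGU {self.ogu_id!r}")


class AdjacencyGraph:
    """Undirected neighbourhood graph over OGU ids (no self loops)."""

    def __init__(self, nodes, edges):
        nodes = list(nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate OGU ids in adjacency nodes")
        node_set = set(nodes)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unregistered OGU")
            g.add_edge(a, b)
        self._g = g

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self._g.edges)

    def neighbors(self, ogu_id: str) -> set[str]:
        return set(self._g.neighbors(ogu_id))

    def has_node(self, ogu_id: str) -> bool:
        return self._g.has_node(ogu_id)

    def is_connected(self) -> bool:
        return nx.is_connected(self._g)

    def connected_components(self, subset=None) -> list[set]:
        g = self._g.subgraph(subset) if subset is not None else self._g
        return [set(c) for c in nx.connected_components(g)]

    def is_contiguous(self, subset) -> bool:
        subset = set(subset)
        if not subset:
            return True
        return len(self.connected_components(subset)) == 1

    def hop_distances(self, sources) -> dict[str, int]:
        """Shortest hop distance from the node set ``sources`` to every node."""
        g = self._g
        lengths = nx.multi_source_dijkstra_path_length(g, set(sources))
        return dict(lengths)

    def cap_neighbors(self, k: int, similarity=None) -> "AdjacencyGraph":
        """Return a copy keeping, per node, only the ``k`` nearest neighbours.

        An edge survives if it is among the k top-ranked for *either*
        endpoint (rank by similarity when given, else lexicographic),
        mirroring a k-nearest-neighbour thinning of the neighbourhood
        matrix.
        """
        keep = set()
        for node in self._g.nodes:
            nbrs = sorted(self._g.neighbors(node))
            if similarity is not None:
                nbrs.sort(key=lambda n: -similarity(node, n))
            for n in nbrs[:k]:
                keep.add(tuple(sorted((node, n))))
        return AdjacencyGraph(self._g.nodes, sorted(keep))

    @classmethod
    def read_edge_list(cls, path, nodes=None) -> "AdjacencyGraph":
        """Read a two-column (ogu_a, ogu_b) delimited edge list."""
        edges = []
        seen_nodes = set()
        with open(path, newline="", encoding="utf-8") as fh:
            dialect = _sniff(fh)
            reader = csv.reader(fh, dialect)
            header = next(reader)
            if header and header[0].lower() in {"ogu_a", "from", "a", "source"}:
                pass  # header row
            else:
                if len(header) >= 2:
                    edges.append((header[0], header[1]))
            for row in reader:
                if not row or not row[0].strip():
                    continue
                edges.append((row[0].strip(), row[1].strip()))
        for a, b in edges:
            seen_nodes.update((a, b))
        return cls(nodes if nodes is not None else sorted(seen_nodes), edges)

    def write_edge_list(self, path):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["ogu_a", "ogu_b"])
            w.writerows(self.edges)

    def __eq__(self, other):
        return isinstance(other, AdjacencyGraph) and self.nodes == other.nodes and self.edges == other.edges


class IncidenceMatrix:
    """Binary species x OGU matrix with registries.

    ``cells[i, j]`` is 1 when species ``species[i]`` is present in OGU
    ``ogus[j]``.  Row/column order is exactly the registry order and is
    preserved through I/O round trips.
    """

    def __init__(self, species, ogus, cells):
        species = [s if isinstance(s, SpeciesRecord) else SpeciesRecord(str(s)) for s in species]
        ogus = [o if isinstance(o, OGU) else OGU(str(o)) for o in ogus]
        cells = np.asarray(cells, dtype=np.int8)
        if cells.shape != (len(species), len(ogus)):
            raise ValueError(
                f"cell shape {cells.shape} does not match registries "
                f"({len(species)} species, {len(ogus)} OGUs)"
            )
        if not np.isin(cells, (0, 1)).all():
            bad = np.argwhere(~np.isin(cells, (0, 1)))[0]
            raise ValueError(f"non-binary cell at row {bad[0]}, column {bad[1]}")
        _check_unique([s.species_id for s in species], "species id")
        _check_unique([o.ogu_id for o in ogus], "OGU id")
        if any("excluded" in s.status_flags for s in species):
            raise ValueError("excluded species may not appear in an incidence matrix")
        self.species = species
        self.ogus = ogus
        self.cells = cells

    # -- registries -------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    @property
    def ogu_ids(self) -> list[str]:
        return [o.ogu_id for o in self.ogus]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def species_index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise KeyError(f"unknown species {species_id!r}") from None

    def ogu_index(self, ogu_id: str) -> int:
        try:
            return self.ogu_ids.index(ogu_id)
        except ValueError:
            raise KeyError(f"unknown OGU {ogu_id!r}") from None

    # -- set views --------------------------------------------------------
    def range_of(self, species_id: str) -> frozenset:
        """Set of OGU ids occupied by a species."""
        row = self.cells[self.species_index(species_id)]
        return frozenset(o for o, v in zip(self.ogu_ids, row) if v)

    def assemblage(self, ogu_id: str) -> frozenset:
        """Set of species ids present in an OGU."""
        col = self.cells[:, self.ogu_index(ogu_id)]
        return frozenset(s for s, v in zip(self.species_ids, col) if v)

    def range_sizes(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    def richness(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def subset_species(self, keep_ids) -> "IncidenceMatrix":
        idx = [i for i, s in enumerate(self.species) if s.species_id in set(keep_ids)]
        return IncidenceMatrix([self.species[i] for i in idx], self.ogus, self.cells[idx])

    def subset_ogus(self, keep_ids) -> "IncidenceMatrix":
        idx = [j for j, o in enumerate(self.ogus) if o.ogu_id in set(keep_ids)]
        return IncidenceMatrix(self.species, [self.ogus[j] for j in idx], self.cells[:, idx])

    def __eq__(self, other):
        return (
            isinstance(other, IncidenceMatrix)
            and self.species_ids == other.species_ids
            and self.ogu_ids == other.ogu_ids
            and np.array_equal(self.cells, other.cells)
        )

    def __repr__(self):
        return f"IncidenceMatrix({len(self.species)} species x {len(self.ogus)} OGUs)"


def _check_unique(ids, what):
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i!r}")
        seen.add(i)


def _sniff(fh) -> csv.Dialect:
    sample = fh.read(4096)
    fh.seek(0)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t")
    except csv.Error:
        class _D(csv.excel):
            delimiter = "\t" if "\t" in sample else ","
        return _D


def read_incidence(path, truthy=TRUTHY_TOKENS, falsy=FALSY_TOKENS) -> IncidenceMatrix:
    """Read a delimited incidence table (species rows, OGU columns).

    The delimiter (comma or tab) is sniffed.  The first column holds
    species ids, the header row OGU ids.  Cell tokens must parse as 0/1.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        dialect = _sniff(fh)
        reader = csv.reader(fh, dialect)
        header = next(reader)
        ogu_ids = [h.strip() for h in header[1:]]
        _check_unique(ogu_ids, "OGU id")
        species_ids, rows = [], []
        for r, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            species_ids.append(row[0].strip())
            vals = []
            for c, tok in enumerate(row[1:], start=1):
                tok = tok.strip().lower()
                if tok in truthy:
                    vals.append(1)
                elif tok in falsy:
                    vals.append(0)
                else:
                    raise ValueError(
                        f"non-binary cell {tok!r} at line {r}, column {header[c]!r}"
                    )
            if len(vals) != len(ogu_ids):
                raise ValueError(f"row {species_ids[-1]!r} has {len(vals)} cells, expected {len(ogu_ids)}")
            rows.append(vals)
        _check_unique(species_ids, "species id")
    m = IncidenceMatrix(species_ids, ogu_ids, np.array(rows, dtype=np.int8))
    logger.info("read incidence: %d species, %d OGUs from %s", *m.shape, path)
    return m


def write_incidence(m: IncidenceMatrix, path, delimiter=","):
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["species"] + m.ogu_ids)
        for sid, row in zip(m.species_ids, m.cells):
            w.writerow([sid] + [int(v) for v in row])


def read_ogu_registry(path) -> list[OGU]:
    """Read an OGU registry CSV (id, name, area_km2, n_qds)."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, dialect=_sniff(fh))
        for row in reader:
            area = row.get("area_km2") or row.get("area")
            n_qds = row.get("n_qds")
            out.append(
                OGU(
                    row["id"].strip(),
                    name=(row.get("name") or "").strip(),
                    area=float(area) if area not in (None, "") else None,
                    n_qds=int(n_qds) if n_qds not in (None, "") else None,
                )
            )
    _check_unique([o.ogu_id for o in out], "OGU id")
    return out


# ---------------------------------------------------------------------------
# QDS-level presence scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QdsCell:
    """One occupied quarter-degree square within an OGU.

    ``margin`` is 'interior' or 'marginal'; ``coast`` is 'coastal' or
    'inland'.  ``neighbor_ogu`` names the adjacent OGU sharing a marginal
    QDS (None when unknown or interior).
    """

    qds_id: str
    margin: str
    coast: str
    neighbor_ogu: str | None = None

    def __post_init__(self):
        if self.margin not in ("interior", "marginal"):
            raise ValueError(f"bad margin tag {self.margin!r}")
        if self.coast not in ("coastal", "inland"):
            raise ValueError(f"bad coast tag {self.coast!r}")


class QdsOccupancy:
    """Fine-grid occupancy: per (species, OGU) the occupied QDS cells."""

    def __init__(self, ogu_qds_totals: dict[str, int]):
        for ogu, n in ogu_qds_totals.items():
            if n <= 0:
                raise ValueError(f"OGU {ogu!r} must have a positive QDS total")
        self.totals = dict(ogu_qds_totals)
        self._occ: dict[tuple[str, str], list[QdsCell]] = {}

    def add(self, species_id: str, ogu_id: str, cell: QdsCell):
        if ogu_id not in self.totals:
            raise KeyError(f"unknown OGU {ogu_id!r}")
        self._occ.setdefault((species_id, ogu_id), []).append(cell)

    def cells(self, species_id: str, ogu_id: str) -> list[QdsCell]:
        return list(self._occ.get((species_id, ogu_id), []))

    @classmethod
    def read_long_csv(cls, path, ogu_qds_totals) -> "QdsOccupancy":
        """Long-format CSV: species, ogu, qds, margin, coast[, neighbor_ogu]."""
        occ = cls(ogu_qds_totals)
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, dialect=_sniff(fh))
            for row in reader:
                occ.add(
                    row["species"].strip(),
                    row["ogu"].strip(),
                    QdsCell(
                        row["qds"].strip(),
                        row["margin"].strip(),
                        row["coast"].strip(),
                        (row.get("neighbor_ogu") or "").strip() or None,
                    ),
                )
        return occ


def score_presence(
    occ: QdsOccupancy,
    species_id: str,
    ogu_id: str,
    neighbor_presence: dict[str, bool] | None = None,
    threshold: float = 0.10,
) -> bool:
    """Decide OGU-level presence from fine-grid occupancy.

    Rules, applied in order:

    1. any occupied interior QDS -> present;
    2. only marginal QDSs, but they cover strictly more than ``threshold``
       of the OGU's QDS total -> present;
    3. only marginal QDSs at or below the threshold, and the species is
       absent from the adjacent OGU(s) sharing those margins -> present;
    4. only marginal QDSs at or below the threshold, but an occupied QDS
       lies on the coastal margin of the species' range -> present;

    otherwise absent.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if ogu_id not in occ.totals:
        raise KeyError(f"unknown OGU {ogu_id!r}")
    cells = occ.cells(species_id, ogu_id)
    if not cells:
        return False
    if any(c.margin == "interior" for c in cells):
        return True
    # marginal-only from here on
    fraction = len(cells) / occ.totals[ogu_id]
    if fraction > threshold:
        return True
    # clause 4 checked before demanding adjacency: coastal margin rescues
    if any(c.coast == "coastal" for c in cells):
        return True
    neighbor_presence = neighbor_presence or {}
    neighbors = {c.neighbor_ogu for c in cells}
    if None in neighbors:
        raise ValueError(
            f"marginal QDS for {species_id!r} in {ogu_id!r} lacks a recorded "
            "neighbouring OGU; adjacency needed to apply the low-coverage rule"
        )
    unknown = neighbors - set(neighbor_presence)
    if unknown:
        raise ValueError(
            f"no presence information for neighbouring OGU(s) {sorted(unknown)}"
        )
    return not any(neighbor_presence[n] for n in neighbors)


# ---------------------------------------------------------------------------
# Taxon ledger
# ---------------------------------------------------------------------------

@dataclass
class LedgerRule:
    kind: str  # exclude | synonymise | merge_complex
    names: tuple
    target: str | None = None


class TaxonLedger:
    """Declarative taxonomic decisions applied before analysis.

    Rule kinds:

    - ``exclude``: drop a species from the analysis set;
    - ``synonymise(junior -> senior)``: junior's range unions into senior;
    - ``merge_complex({a, b, ...} -> c)``: members union into a new
      complex taxon named ``c``.
    """

    def __init__(self, rules: list[LedgerRule] | None = None):
        self.rules = list(rules or [])

    def exclude(self, name):
        self.rules.append(LedgerRule("exclude", (name,)))
        return self

    def synonymise(self, junior, senior):
        self.rules.append(LedgerRule("synonymise", (junior,), senior))
        return self

    def merge_complex(self, members, new_name):
        self.rules.append(LedgerRule("merge_complex", tuple(members), new_name))
        return self

    @classmethod
    def from_config(cls, block: dict) -> "TaxonLedger":
        """Build from a config block (e.g. parsed YAML).

        Expected keys: ``exclude`` (list of names), ``synonymise`` (list of
        {junior, senior}), ``merge_complex`` (list of {members, name}).
        """
        ledger = cls()
        for name in block.get("exclude", []) or []:
            ledger.exclude(name)
        for rule in block.get("synonymise", []) or []:
            ledger.synonymise(rule["junior"], rule["senior"])
        for rule in block.get("merge_complex", []) or []:
            ledger.merge_complex(rule["members"], rule["name"])
        return ledger

    def validate(self, known_names):
        known = set(known_names)
        touched: dict[str, str] = {}
        for rule in self.rules:
            refs = set(rule.names)
            if rule.kind == "synonymise":
                refs.add(rule.target)
            missing = refs - known
            if missing:
                raise ValueError(f"ledger rule references unknown name(s) {sorted(missing)}")
            for n in rule.names:
                if n in touched:
                    raise ValueError(
                        f"conflicting ledger rules on {n!r} ({touched[n]} vs {rule.kind})"
                    )
                touched[n] = rule.kind


def apply_taxon_ledger(registry, ledger: TaxonLedger, matrix: IncidenceMatrix | None = None):
    """Apply ledger rules to a species registry (and optionally a matrix).

    Returns the analysis registry; with ``matrix`` given, returns
    ``(registry, matrix)`` where merged/synonymised taxa have the union
    (logical OR) of their members' ranges.
    """
    registry = [s if isinstance(s, SpeciesRecord) else SpeciesRecord(str(s)) for s in registry]
    by_id = {s.species_id: s for s in registry}
    ledger.validate(by_id)

    drop: set[str] = set()
    # groups: representative id -> (member ids, flags, display name)
    groups: dict[str, dict] = {}
    for rule in ledger.rules:
        if rule.kind == "exclude":
            drop.add(rule.names[0])
        elif rule.kind == "synonymise":
            junior, senior = rule.names[0], rule.target
            drop.add(junior)
            groups.setdefault(senior, {"members": {senior}, "flags": set(), "name": None})
            groups[senior]["members"].add(junior)
            groups[senior]["flags"].add("synonymised")
        elif rule.kind == "merge_complex":
            rep = rule.names[0]
            for n in rule.names[1:]:
                drop.add(n)
            groups[rep] = {
                "members": set(rule.names),
                "flags": {"merged_complex"},
                "name": rule.target,
            }

    out_registry = []
    for s in registry:
        if s.species_id in drop:
            continue
        if s.species_id in groups:
            g = groups[s.species_id]
            s = replace(
                s,
                species_id=g["name"] or s.species_id,
                name=g["name"] or s.name,
                status_flags=frozenset(s.status_flags | g["flags"]),
            )
        out_registry.append(s)
    logger.info("taxon ledger: %d -> %d analysis taxa", len(registry), len(out_registry))

    if matrix is None:
        return out_registry

    new_cells = []
    kept = []
    consumed = set(drop)
    for s in registry:
        sid = s.species_id
        if sid in consumed and sid not in groups:
            continue
        if sid in groups:
            member_rows = [
                matrix.cells[matrix.species_index(mid)] for mid in sorted(groups[sid]["members"])
            ]
            new_cells.append(np.clip(np.sum(member_rows, axis=0), 0, 1))
        else:
            new_cells.append(matrix.cells[matrix.species_index(sid)])
        kept.append(sid)
    final_registry = []
    for sid in kept:
        rec = by_id[sid]
        if sid in groups:
            g = groups[sid]
            rec = replace(
                rec,
                species_id=g["name"] or sid,
                name=g["name"] or rec.name,
                status_flags=frozenset(rec.status_flags | g["flags"]),
            )
        final_registry.append(rec)
    new_matrix = IncidenceMatrix(final_registry, matrix.ogus, np.array(new_cells, dtype=np.int8))
    return final_registry, new_matrix


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

@dataclass
class PruneReport:
    dropped_species: list = field(default_factory=list)  # (id, reason)
    dropped_ogus: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def singleton_species(self) -> dict[str, str]:
        """Map species id -> its single OGU, for later reconsideration."""
        return {sid: why.split(":", 1)[1] for sid, why in self.dropped_species if why.startswith("singleton:")}


def prune_matrix(
    m: IncidenceMatrix,
    drop_empty_ogus: bool = True,
    drop_uninformative_species: bool = False,
) -> tuple[IncidenceMatrix, PruneReport]:
    """Remove empty OGUs and/or uninformative species.

    Uninformative species are those absent everywhere, present everywhere,
    or restricted to a single OGU (the latter recorded with their OGU so
    downstream analyses can reconsider them).  Removals cascade (dropping
    a species can empty an OGU, which can make another species constant),
    so passes repeat until a fixed point; the result is idempotent.
    """
    out = m
    report = PruneReport()
    while True:
        out, step = _prune_once(out, drop_empty_ogus, drop_uninformative_species)
        report.dropped_species.extend(step.dropped_species)
        report.dropped_ogus.extend(step.dropped_ogus)
        report.warnings = step.warnings
        if not step.dropped_species and not step.dropped_ogus:
            return out, report


def _prune_once(
    m: IncidenceMatrix,
    drop_empty_ogus: bool,
    drop_uninformative_species: bool,
) -> tuple[IncidenceMatrix, PruneReport]:
    report = PruneReport()
    keep_species = []
    n_ogus = len(m.ogus)
    for i, s in enumerate(m.species):
        r = int(m.cells[i].sum())
        if drop_uninformative_species and r == 0:
            report.dropped_species.append((s.species_id, "empty"))
        elif drop_uninformative_species and r == n_ogus:
            report.dropped_species.append((s.species_id, "constant"))
        elif drop_uninformative_species and r == 1:
            ogu = m.ogu_ids[int(np.argmax(m.cells[i]))]
            report.dropped_species.append((s.species_id, f"singleton:{ogu}"))
        elif r == 0 and not drop_uninformative_species:
            keep_species.append(i)  # kept, but flagged
            report.warnings.append(f"species {s.species_id!r} has an empty range")
        else:
            keep_species.append(i)
    cells = m.cells[keep_species]
    species = [m.species[i] for i in keep_species]

    keep_ogus = list(range(n_ogus))
    if drop_empty_ogus:
        col_sums = cells.sum(axis=0) if len(species) else np.zeros(n_ogus)
        keep_ogus = [j for j in range(n_ogus) if col_sums[j] > 0]
        for j in range(n_ogus):
            if j not in keep_ogus:
                report.dropped_ogus.append(m.ogu_ids[j])
    out = IncidenceMatrix(species, [m.ogus[j] for j in keep_ogus], cells[:, keep_ogus])
    if 0 in out.shape:
        report.warnings.append("pruning produced an empty matrix")
    return out, report
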