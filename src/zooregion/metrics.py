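"""Per-OGU endemism surfaces and Jenks natural-breaks classing.

Surfaces: species richness, dominion endemism (species whose whole range
lies inside a reference region), narrow endemism (count of narrow-flagged
species), weighted endemism (WE, sum of inverse range sizes) and
richness-corrected WE.  Each surface can be min-max normalised and
partitioned into classes by a Fisher-Jenks dynamic programme that
minimises within-class sum of squared deviations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from zooregion.incidence import IncidenceMatrix


@dataclass
class MetricSurface:
    metric_name: str
    ogu_ids: list
    raw: np.ndarray
    excluded: list = field(default_factory=list)  # OGUs with undefined values

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.raw) != len(self.ogu_ids):
            raise ValueError("surface length mismatch")

    def value(self, ogu_id) -> float:
        return float(self.raw[self.ogu_ids.index(ogu_id)])

    def normalised(self) -> np.ndarray:
        """Min-max normalisation to [0, 1]; constant surfaces map to 0."""
        defined = ~np.isnan(self.raw)
        out = np.full_like(self.raw, np.nan)
        if defined.any():
            lo, hi = self.raw[defined].min(), self.raw[defined].max()
            out[defined] = (self.raw[defined] - lo) / (hi - lo) if hi > lo else 0.0
        return out

    def classes(self, k: int = 5) -> np.ndarray:
        """Jenks class index (1..k) per OGU; NaN values get class 0."""
        defined = ~np.isnan(self.raw)
        vals = self.raw[defined]
        k_eff = min(k, len(np.unique(vals)))
        _, assign = jenks_breaks(vals, k_eff)
        out = np.zeros(len(self.raw), dtype=int)
        out[defined] = assign
        return out

    def write_tsv(self, path, k: int = 5):
        norm = self.normalised()
        cls = self.classes(k)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["ogu", "raw", "normalised", "class"])
            for ogu, r, n, c in zip(self.ogu_ids, self.raw, norm, cls):
                w.writerow([ogu, f"{r:.6g}", "" if np.isnan(n) else f"{n:.6g}", c])


def species_richness(m: IncidenceMatrix) -> MetricSurface:
    """Count of species present per OGU."""
    return MetricSurface("richness", list(m.ogu_ids), m.richness().astype(float))


def dominion_endemism(m: IncidenceMatrix, dominion) -> MetricSurface:
    """Per-OGU count of present species whose entire range lies inside
    ``dominion``; species straddling the boundary count nowhere."""
    dominion = set(dominion)
    unknown = dominion - set(m.ogu_ids)
    if unknown:
        raise ValueError(f"dominion references unknown OGU(s) {sorted(unknown)}")
    inside = np.array([m.range_of(s) <= dominion and bool(m.range_of(s)) for s in m.species_ids])
    counts = m.cells[inside].sum(axis=0).astype(float) if inside.any() else np.zeros(len(m.ogus))
    return MetricSurface("dominion_endemism", list(m.ogu_ids), counts)


@dataclass(frozen=True)
class NarrowFlag:
    species_id: str
    flagged: bool
    provenance: str  # single_ogu | cone_restricted | half_coe_range | override | none


def narrow_endemism_flags(
    m: IncidenceMatrix, centres=None, overrides: dict | None = None
) -> dict[str, NarrowFlag]:
    """Flag narrow endemic species.

    Rules in order: restricted to a single OGU; restricted to a CONE;
    occupying less than half the range of a COE it is endemic to.  Ledger
    overrides ('narrow' / 'not_narrow') take precedence.
    """
    overrides = overrides or {}
    for sid, ov in overrides.items():
        if ov not in ("narrow", "not_narrow"):
            raise ValueError(f"bad override {ov!r} for {sid!r}")
    cone_sets = []
    coe_sets = []
    if centres is not None:
        cone_sets = [c.members for c in centres.centres if c.kind == "CONE"]
        coe_sets = [c.members for c in centres.centres if c.kind == "COE"]
    flags: dict[str, NarrowFlag] = {}
    for sid in m.species_ids:
        rng = m.range_of(sid)
        ov = overrides.get(sid)
        if ov == "narrow":
            flags[sid] = NarrowFlag(sid, True, "override")
            continue
        if ov == "not_narrow":
            flags[sid] = NarrowFlag(sid, False, "override")
            continue
        if not rng:
            flags[sid] = NarrowFlag(sid, False, "none")
            continue
        if len(rng) == 1:
            flags[sid] = NarrowFlag(sid, True, "single_ogu")
        elif any(rng <= cs for cs in cone_sets):
            flags[sid] = NarrowFlag(sid, True, "cone_restricted")
        elif any(rng <= cs and len(rng) < len(cs) / 2 for cs in coe_sets):
            flags[sid] = NarrowFlag(sid, True, "half_coe_range")
        else:
            flags[sid] = NarrowFlag(sid, False, "none")
    return flags


def narrow_endemism(m: IncidenceMatrix, flags: dict[str, NarrowFlag]) -> MetricSurface:
    """Per-OGU count of present narrow-flagged species."""
    mask = np.array([flags[s].flagged if s in flags else False for s in m.species_ids])
    counts = m.cells[mask].sum(axis=0).astype(float) if mask.any() else np.zeros(len(m.ogus))
    return MetricSurface("narrow_endemism", list(m.ogu_ids), counts)


def weighted_endemism(m: IncidenceMatrix) -> MetricSurface:
    """WE(u) = sum over species present in u of 1 / range size.

    Conservation identity: the WE values sum to the number of species with
    non-empty ranges.
    """
    sizes = m.range_sizes().astype(float)
    with np.errstate(divide="ignore"):
        inv = np.where(sizes > 0, 1.0 / np.maximum(sizes, 1), 0.0)
    we = inv @ m.cells
    return MetricSurface("weighted_endemism", list(m.ogu_ids), we.astype(float))


def corrected_weighted_endemism(we: MetricSurface, richness: MetricSurface) -> MetricSurface:
    """CWE(u) = WE(u) / richness(u); OGUs with zero richness are excluded."""
    if we.ogu_ids != richness.ogu_ids:
        raise ValueError("surfaces cover different OGU sets")
    out = np.full(len(we.raw), np.nan)
    excluded = []
    for i, (w, r) in enumerate(zip(we.raw, richness.raw)):
        if r > 0:
            out[i] = w / r
        else:
            excluded.append(we.ogu_ids[i])
    return MetricSurface("corrected_weighted_endemism", list(we.ogu_ids), out, excluded)


# ---------------------------------------------------------------------------
# Jenks natural breaks (Fisher dynamic programming on distinct values)
# ---------------------------------------------------------------------------

def jenks_breaks(values, k: int) -> tuple[list[float], np.ndarray]:
    """Optimal k-class partition minimising within-class SSD.

    The programme runs on distinct sorted values with multiplicities, so
    tied values can never be split across classes.  Returns
    (class upper-bound break values, class index 1..k per input value).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("values must be a non-empty 1-D array")
    uniq, counts = np.unique(values, return_counts=True)
    nu = len(uniq)
    if k > nu:
        raise ValueError(f"k={k} exceeds the {nu} distinct values")
    if k < 1:
        raise ValueError("k must be >= 1")

    # prefix sums over weighted distinct values
    w = counts.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * uniq)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * uniq**2)])

    def ssd(i: int, j: int) -> float:
        """Weighted SSD of distinct values i..j-1 (half-open)."""
        n = cw[j] - cw[i]
        s = cwx[j] - cwx[i]
        s2 = cwx2[j] - cwx2[i]
        return s2 - s * s / n

    INF = float("inf")
    cost = np.full((k + 1, nu + 1), INF)
    back = np.zeros((k + 1, nu + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, nu + 1):
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                if v < cost[c, j] - 1e-12:
                    cost[c, j] = v
                    back[c, j] = i
    # recover break positions
    cuts = []
    j = nu
    for c in range(k, 0, -1):
        i = back[c, j]
        cuts.append((i, j))
        j = i
    cuts.reverse()
    breaks = [float(uniq[j - 1]) for _, j in cuts]  # upper bound value per class
    class_of_value = {}
    for ci, (i, j) in enumerate(cuts, start=1):
        for u in uniq[i:j]:
            class_of_value[float(u)] = ci
    assign = np.array([class_of_value[float(v)] for v in values], dtype=int)
    return breaks, assign
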