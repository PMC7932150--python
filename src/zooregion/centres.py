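"""Centres of endemism and the characteristic/narrow endemic classifier.

Two kinds of centres are delineated from the regionalisation:

- COE (centre of endemism): a district-level region harbouring at least
  four species endemic to it;
- CONE (centre of narrow endemism): a single OGU, or a tight cluster of
  OGUs merged above the district similarity, harbouring at least two
  narrowly endemic species.

Endemics of a centre are labelled *characteristic* when their range
roughly fills the centre and *narrow* when confined to a small fraction
of it; per-species ledger overrides take precedence over the geometric
rules.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import pandas as pd

from zooregion.incidence import IncidenceMatrix
from zooregion.regions import RegionHierarchy
from zooregion.similarity import Dendrogram

REGION_FIXTURE_CODES = {"E": "endemic", "P": "present", "NE": "near_endemic", "-": "blank"}


@dataclass(frozen=True)
class EndemicStatus:
    species_id: str
    region: str
    status: str  # endemic | near_endemic | non_endemic

    def __post_init__(self):
        if self.status not in ("endemic", "near_endemic", "non_endemic"):
            raise ValueError(f"bad status {self.status!r}")


@dataclass
class RegionSummary:
    region: str
    n_endemics: int
    n_present: int

    @property
    def pct_endemicity(self) -> float:
        if self.n_present == 0:
            return float("nan")
        return round(100.0 * self.n_endemics / self.n_present, 1)


def classify_endemics(
    m: IncidenceMatrix, region, spillover: float = 0.0, region_name: str = "region"
) -> tuple[list[EndemicStatus], RegionSummary]:
    """Per-species endemic status with respect to an OGU set.

    A species is *endemic* when every occupied OGU lies inside the region,
    *near-endemic* when the fraction of occupied OGUs outside is positive
    but at most ``spillover`` (only when spillover > 0), otherwise
    *non-endemic*.  Species absent from the region are non-endemic and do
    not count towards the region's species-present denominator.
    """
    region = set(region)
    if not region:
        raise ValueError("empty region")
    unknown = region - set(m.ogu_ids)
    if unknown:
        raise ValueError(f"region references unknown OGU(s) {sorted(unknown)}")
    statuses = []
    n_endemic = n_present = 0
    for sid in m.species_ids:
        rng = m.range_of(sid)
        if not rng or not (rng & region):
            statuses.append(EndemicStatus(sid, region_name, "non_endemic"))
            continue
        n_present += 1
        outside = len(rng - region) / len(rng)
        if outside == 0:
            status = "endemic"
            n_endemic += 1
        elif spillover > 0 and outside <= spillover:
            status = "near_endemic"
        else:
            status = "non_endemic"
        statuses.append(EndemicStatus(sid, region_name, status))
    return statuses, RegionSummary(region_name, n_endemic, n_present)


def summarise_endemism(m: IncidenceMatrix, regions: dict) -> pd.DataFrame:
    """Per-species endemic flags for several named regions, plus totals.

    ``regions`` maps region name -> OGU set.  Returns a DataFrame with one
    row per species (True/False per region) and three appended rows:
    ``Total endemics``, ``Total species`` (present) and
    ``Species endemicity (%)``.
    """
    if not regions:
        raise ValueError("no regions given")
    cols = {}
    totals, presents, pcts = {}, {}, {}
    for name, ogus in regions.items():
        statuses, summary = classify_endemics(m, ogus, region_name=name)
        cols[name] = [st.status == "endemic" for st in statuses]
        totals[name] = summary.n_endemics
        presents[name] = summary.n_present
        pcts[name] = summary.pct_endemicity
    df = pd.DataFrame(cols, index=m.species_ids, dtype=object)
    df.loc["Total endemics"] = totals
    df.loc["Total species"] = presents
    df.loc["Species endemicity (%)"] = pcts
    return df


# ---------------------------------------------------------------------------
# Centres
# ---------------------------------------------------------------------------

@dataclass
class Centre:
    kind: str  # COE | CONE
    name: str
    members: frozenset
    endemics: list = field(default_factory=list)
    labels: dict = field(default_factory=dict)  # species -> characteristic|narrow|other

    def __post_init__(self):
        if self.kind not in ("COE", "CONE"):
            raise ValueError(f"bad centre kind {self.kind!r}")


@dataclass
class CentreSet:
    centres: list[Centre] = field(default_factory=list)

    def of_kind(self, kind):
        return [c for c in self.centres if c.kind == kind]

    def write_tsv(self, path):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["kind", "name", "members", "n_endemics", "endemics", "labels"])
            for c in self.centres:
                w.writerow(
                    [
                        c.kind,
                        c.name,
                        " ".join(sorted(c.members)),
                        len(c.endemics),
                        " ".join(c.endemics),
                        " ".join(f"{s}={l}" for s, l in sorted(c.labels.items())),
                    ]
                )


def identify_coes(
    h: RegionHierarchy, m: IncidenceMatrix, min_endemics: int = 4, level: str = "district"
) -> CentreSet:
    """Districts with >= ``min_endemics`` endemic species become COEs."""
    out = CentreSet()
    for region in h.at_level(level):
        members = region.all_members & set(m.ogu_ids)
        if not members:
            continue
        statuses, summary = classify_endemics(m, members, region_name=region.name)
        if summary.n_endemics >= min_endemics:
            endemics = [st.species_id for st in statuses if st.status == "endemic"]
            out.centres.append(Centre("COE", region.name, frozenset(members), endemics))
    return out


def identify_cones(
    d: Dendrogram,
    m: IncidenceMatrix,
    narrow_flags: dict,
    district_threshold: float,
    min_narrow: int = 2,
    max_extent: int = 3,
) -> CentreSet:
    """Single OGUs or tight clusters holding >= ``min_narrow`` narrow endemics.

    Candidate units are single OGUs plus dendrogram clusters merged at a
    similarity strictly above the district phenon line, capped at
    ``max_extent`` member OGUs.  A candidate becomes a CONE when at least
    ``min_narrow`` narrow-flagged species are endemic to it.
    """
    candidates = {frozenset([o]) for o in m.ogu_ids}
    for cluster, height in d.subtree_heights().items():
        if 1 < len(cluster) <= max_extent and (1.0 - height) > district_threshold:
            candidates.add(frozenset(cluster) & set(m.ogu_ids))
    out = CentreSet()
    taken: set = set()
    for cand in sorted(candidates, key=lambda c: (len(c), sorted(c))):
        if not cand:
            continue
        narrows = [
            sid
            for sid, flagged in narrow_flags.items()
            if flagged and m.range_of(sid) and m.range_of(sid) <= cand
        ]
        if len(narrows) >= min_narrow and not (cand & taken):
            name = "-".join(sorted(cand))
            out.centres.append(Centre("CONE", name, cand, sorted(narrows)))
            taken |= cand
    return out


def classify_characteristic_narrow(
    centre: Centre,
    m: IncidenceMatrix | None = None,
    areas: dict | None = None,
    cones: CentreSet | None = None,
    overrides: dict | None = None,
    descriptors: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Label each centre endemic characteristic / narrow / other.

    With an incidence matrix the geometric evidence is computed from
    occupied-OGU fractions (plus OGU areas when given); alternatively a
    ``descriptors`` table supplies the same quantities directly (columns:
    species, n_occupied, centre_n_ogus, area_fraction, cone_restricted,
    override).

    Rules (extent evidence takes precedence over OGU counts when area
    information is available, since a species may touch every member OGU
    of a centre while occupying a sliver of its extent):

    - characteristic: occupied-area fraction > 1/2 of the centre's extent;
      or, without area data, occupied-OGU fraction > 2/3;
    - narrow: restricted to a single OGU, to a nested CONE, or to less
      than half the centre's range;
    - overrides: ``override_narrow`` forces narrow, ``override_not_narrow``
      blocks narrow; neither forces characteristic.
    """
    overrides = overrides or {}
    labels: dict[str, str] = {}
    rows = _centre_evidence(centre, m, areas, cones, descriptors)
    for sid, ev in rows.items():
        ov = overrides.get(sid, ev.get("override", ""))
        if ov == "narrow":
            labels[sid] = "narrow"
            continue
        characteristic = (
            ev["area_fraction"] > 0.5
            if ev["area_fraction"] is not None
            else ev["ogu_fraction"] > 2 / 3
        )
        if characteristic:
            labels[sid] = "characteristic"
            continue
        narrow = (
            ev["n_occupied"] == 1
            or ev["cone_restricted"]
            or (
                ev["area_fraction"] is not None
                and ev["area_fraction"] < 0.5
            )
            or (ev["area_fraction"] is None and ev["ogu_fraction"] < 0.5)
        )
        if narrow and ov != "not_narrow":
            labels[sid] = "narrow"
        else:
            labels[sid] = "other"
    return labels


def _centre_evidence(centre, m, areas, cones, descriptors):
    rows = {}
    if descriptors is not None:
        for _, r in descriptors.iterrows():
            area_fraction = r.get("area_fraction")
            if pd.isna(area_fraction):
                area_fraction = None
            rows[r["species"]] = {
                "n_occupied": int(r["n_occupied"]),
                "ogu_fraction": int(r["n_occupied"]) / int(r["centre_n_ogus"]),
                "area_fraction": area_fraction,
                "cone_restricted": bool(r.get("cone_restricted", False)),
                "override": (r.get("override") or ""),
            }
        return rows
    if m is None:
        raise ValueError("either an incidence matrix or a descriptors table is required")
    cone_sets = [c.members for c in (cones.centres if cones else [])]
    centre_area = (
        sum(areas[o] for o in centre.members) if areas is not None else None
    )
    for sid in centre.endemics:
        rng = m.range_of(sid) & centre.members
        area_fraction = (
            sum(areas[o] for o in rng) / centre_area
            if areas is not None and centre_area
            else None
        )
        rows[sid] = {
            "n_occupied": len(rng),
            "ogu_fraction": len(rng) / len(centre.members),
            "area_fraction": area_fraction,
            "cone_restricted": any(rng <= cs for cs in cone_sets),
            "override": "",
        }
    return rows


# ---------------------------------------------------------------------------
# Packaged fixtures (per-species regional status; COE-restricted descriptors)
# ---------------------------------------------------------------------------

def load_status_fixture(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a per-species regional endemic-status table.

    The TSV has columns ``family``, ``species`` then one column per
    region with codes E (endemic), P (present, non-endemic), NE
    (near-endemic) and ``-`` (no mark).  Comment lines of the form
    ``# species_present: <region>=<count> ...`` carry the per-region
    species-present totals, which cannot be derived from the marks alone.
    """
    presents: dict[str, int] = {}
    rows = []
    header = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# species_present:"):
                for tok in line.split(":", 1)[1].split():
                    k, v = tok.split("=")
                    presents[k] = int(v)
                continue
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            rows.append(parts)
    df = pd.DataFrame(rows, columns=header)
    for col in header[2:]:
        bad = set(df[col]) - set(REGION_FIXTURE_CODES)
        if bad:
            raise ValueError(f"unknown status code(s) {sorted(bad)} in column {col!r}")
    return df, presents


def summarise_status_fixture(df: pd.DataFrame, presents: dict[str, int]) -> list[RegionSummary]:
    """Totals and percentage endemicity per region column of a status fixture."""
    out = []
    for col in df.columns[2:]:
        n_endemic = int((df[col] == "E").sum())
        out.append(RegionSummary(col, n_endemic, presents[col]))
    return out


def load_centre_fixture(path) -> pd.DataFrame:
    """Read a COE-restricted species descriptor table (TSV).

    Columns: species, family, centre, centre_n_ogus, n_occupied,
    cone_restricted (0/1), area_fraction (float or empty), override
    ('', narrow, not_narrow).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"cone_restricted": int})
    df["override"] = df["override"].fillna("")
    return df


def classify_centre_fixture(df: pd.DataFrame) -> dict[str, str]:
    """Run the characteristic/narrow classifier over a descriptor fixture."""
    labels: dict[str, str] = {}
    for centre_name, group in df.groupby("centre", sort=False):
        centre = Centre("COE", centre_name, frozenset(), list(group["species"]))
        labels.update(classify_characteristic_narrow(centre, descriptors=group))
    return labels
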