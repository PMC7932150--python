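"""Biotic element analysis.

Pairwise distances between species ranges feed three stages: (1) the
*distratio* clustering statistic -- the mean of the smallest fraction of
pairwise distances over the mean of the largest fraction -- tested
against a spatially autocorrelated null model that regrows every range as
a connected set on the OGU adjacency graph; (2) a nonmetric
multidimensional scaling of the distance matrix; (3) clustering of the
NMDS configuration with a Gaussian mixture extended by a uniform noise
component, the component count chosen by BIC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.manifold import MDS

from zooregion.incidence import AdjacencyGraph, IncidenceMatrix

METRICS = ("kulczynski", "jaccard")


@dataclass
class RangeDistanceMatrix:
    species_ids: list
    values: np.ndarray
    metric_name: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("distances must lie in [0, 1]")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def range_distance(m: IncidenceMatrix, metric: str = "kulczynski") -> RangeDistanceMatrix:
    """Pairwise distances between species ranges.

    kulczynski: d(A, B) = 1 - (|A&B|/|A| + |A&B|/|B|) / 2
    jaccard:    d(A, B) = 1 - |A&B| / |A|B|
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    sizes = m.cells.sum(axis=1)
    empty = [m.species_ids[i] for i in np.flatnonzero(sizes == 0)]
    if empty:
        raise ValueError(f"species with empty range: {empty}")
    x = m.cells.astype(np.float64)
    inter = x @ x.T
    if metric == "kulczynski":
        d = 1.0 - 0.5 * (inter / sizes[:, None] + inter / sizes[None, :])
    else:
        union = sizes[:, None] + sizes[None, :] - inter
        d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return RangeDistanceMatrix(list(m.species_ids), d, metric)


def distratio(d: RangeDistanceMatrix | np.ndarray, prop: float = 0.25) -> float:
    """t = mean(smallest ceil(prop*N) distances) / mean(largest ceil(prop*N)).

    Small t indicates clustered ranges.  Scale-invariant; t in (0, 1].
    """
    if not 0 < prop <= 0.5:
        raise ValueError("prop must lie in (0, 0.5]")
    vals = d.condensed() if isinstance(d, RangeDistanceMatrix) else np.asarray(d, dtype=float)
    n = vals.size
    if n < math.ceil(1.0 / prop):
        raise ValueError(f"need at least {math.ceil(1.0 / prop)} pairwise distances")
    k = math.ceil(prop * n)
    s = np.sort(vals)
    top = s[-k:].mean()
    if top == 0:
        raise ValueError("all distances are zero (degenerate matrix)")
    return float(s[:k].mean() / top)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

def _grow_connected_range(g: AdjacencyGraph, size: int, rng, nodes: list) -> set:
    """Connected random range: uniform seed OGU, then uniform random
    expansion to a neighbour of the current set."""
    start = nodes[rng.integers(len(nodes))]
    chosen = {start}
    frontier = set(g.neighbors(start))
    while len(chosen) < size:
        if not frontier:
            raise ValueError("graph too small or disconnected for requested range size")
        pick = sorted(frontier)[rng.integers(len(frontier))]
        chosen.add(pick)
        frontier |= g.neighbors(pick)
        frontier -= chosen
    return chosen


def simulate_null_ranges(
    m: IncidenceMatrix, g: AdjacencyGraph, n_sim: int, seed: int = 0
) -> list[IncidenceMatrix]:
    """Null replicates preserving the observed range-size multiset exactly.

    Each species' range is regrown as a connected set on the adjacency
    graph (spatial autocorrelation) with its observed size.
    """
    nodes = sorted(g.nodes)
    missing = set(m.ogu_ids) - set(nodes)
    if missing:
        raise ValueError(f"adjacency graph lacks OGU(s) {sorted(missing)}")
    if not g.is_connected():
        raise ValueError("adjacency graph must be connected")
    sizes = m.range_sizes()
    if sizes.max(initial=0) > len(nodes):
        raise ValueError("a range size exceeds the number of OGUs")
    rng = np.random.default_rng(seed)
    col_index = {o: j for j, o in enumerate(m.ogu_ids)}
    out = []
    for _ in range(n_sim):
        cells = np.zeros_like(m.cells)
        for i, size in enumerate(sizes):
            if size == 0:
                continue
            for o in _grow_connected_range(g, int(size), rng, nodes):
                cells[i, col_index[o]] = 1
        out.append(IncidenceMatrix(m.species, m.ogus, cells))
    return out


@dataclass
class ClusteringTestResult:
    t_observed: float
    t_simulated: list[float]
    p_value: float
    n_sim: int
    prop: float
    metric: str
    seed: int

    def to_json(self) -> str:
        sims = np.asarray(self.t_simulated)
        return json.dumps(
            {
                "t_observed": self.t_observed,
                "p_value": self.p_value,
                "n_sim": self.n_sim,
                "prop": self.prop,
                "metric": self.metric,
                "seed": self.seed,
                "null_mean": float(sims.mean()),
                "null_min": float(sims.min()),
                "null_max": float(sims.max()),
            },
            indent=2,
        )


def clustering_test(
    m: IncidenceMatrix,
    g: AdjacencyGraph,
    n_sim: int = 1000,
    seed: int = 0,
    prop: float = 0.25,
    metric: str = "kulczynski",
) -> ClusteringTestResult:
    """Monte-Carlo test for clustering of distribution areas.

    One-sided for small t, with the (1 + B)/(1 + n_sim) correction so p
    never reaches zero.
    """
    t_obs = distratio(range_distance(m, metric), prop)
    sims = []
    for rep in simulate_null_ranges(m, g, n_sim, seed):
        sims.append(distratio(range_distance(rep, metric), prop))
    b = sum(1 for t in sims if t <= t_obs)
    p = (1.0 + b) / (1.0 + n_sim)
    return ClusteringTestResult(t_obs, sims, p, n_sim, prop, metric, seed)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    coords: np.ndarray
    stress: float  # Kruskal stress-1


def nmds(
    d: RangeDistanceMatrix, dims: int = 2, n_restarts: int = 4, seed: int = 0
) -> NmdsResult:
    """Nonmetric MDS (Kruskal stress-1, majorization with monotone
    regression); best configuration over ``n_restarts`` random starts."""
    n = len(d.species_ids)
    if n < dims + 1:
        raise ValueError("need more species than embedding dimensions")
    model = MDS(
        n_components=dims,
        metric_mds=False,
        metric="precomputed",
        n_init=n_restarts,
        init="random",
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
        eps=1e-9,
    )
    coords = model.fit_transform(d.values)
    return NmdsResult(coords, float(model.stress_))


# ---------------------------------------------------------------------------
# Mixture-with-noise clustering
# ---------------------------------------------------------------------------

@dataclass
class BioticElementSet:
    species_ids: list
    assignments: list  # per species: 1..K or "noise"
    coords: np.ndarray
    n_elements: int
    bic: float = float("nan")

    def members(self, element) -> list:
        return [s for s, a in zip(self.species_ids, self.assignments) if a == element]

    def write_tsv(self, path):
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["species", "element"] + [f"dim{i+1}" for i in range(self.coords.shape[1])])
            for sid, a, xy in zip(self.species_ids, self.assignments, self.coords):
                w.writerow([sid, a] + [f"{v:.6g}" for v in xy])


def _fit_mixture_with_noise(x: np.ndarray, k: int, rng, n_init: int = 3):
    """EM for k spherical-ish (full-covariance) Gaussians plus a uniform
    noise component over the bounding box.  Returns (loglik, n_params,
    responsibilities)."""
    n, dims = x.shape
    lo, hi = x.min(axis=0), x.max(axis=0)
    # pad the uniform support beyond the data range so cluster fringes are
    # not swallowed by the noise component
    span = np.maximum(hi - lo, 1e-9) * 2.0
    log_unif = -float(np.log(span).sum())
    best = None
    for _ in range(n_init):
        means = x[rng.choice(n, size=k, replace=False)]
        if k > 1:
            km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
            km.fit(x)
            means = km.cluster_centers_
        covs = np.array([np.cov(x.T) + np.eye(dims) * 1e-6 for _ in range(k)])
        weights = np.full(k + 1, 1.0 / (k + 1))
        loglik = -np.inf
        for _it in range(300):
            logp = np.empty((n, k + 1))
            for j in range(k):
                logp[:, j] = np.log(weights[j] + 1e-300) + _log_gauss(x, means[j], covs[j])
            logp[:, k] = np.log(weights[k] + 1e-300) + log_unif
            mx = logp.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
            new_loglik = float(lse.sum())
            resp = np.exp(logp - lse[:, None])
            if new_loglik - loglik < 1e-8:
                loglik = new_loglik
                break
            loglik = new_loglik
            nk = resp.sum(axis=0)
            weights = nk / n
            for j in range(k):
                if nk[j] < 1e-9:
                    continue
                means[j] = resp[:, j] @ x / nk[j]
                diff = x - means[j]
                covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j]
                covs[j] += np.eye(dims) * 1e-6
        # a Gaussian supported by fewer points than dims+1 is degenerate
        # (covariance collapse onto an outlier); such fits are invalid
        nk = resp.sum(axis=0)
        valid = bool((nk[:k] >= dims + 1).all())
        if best is None or (valid, loglik) > (best[2], best[0]):
            best = (loglik, resp, valid)
    n_params = k * (dims + dims * (dims + 1) // 2) + k  # means, covs, free weights
    return best[0], n_params, best[1], best[2]


def _log_gauss(x, mean, cov):
    dims = x.shape[1]
    diff = x - mean
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = cov + np.eye(dims) * 1e-6
        chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, diff.T)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (dims * np.log(2 * np.pi) + logdet + (sol**2).sum(axis=0))


def cluster_elements(
    coords: np.ndarray, max_k: int = 10, seed: int = 0, species_ids=None
) -> BioticElementSet:
    """Assign species to biotic elements or the noise class.

    Gaussian mixture with a uniform noise component; K chosen by BIC over
    1..max_k.  A species lands in the noise class when the uniform
    component carries its largest responsibility.
    """
    x = np.asarray(coords, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("coordinates must be finite")
    n = x.shape[0]
    if species_ids is None:
        species_ids = [f"sp{i}" for i in range(n)]
    rng = np.random.default_rng(seed)
    best = None
    fallback = None
    for k in range(1, min(max_k, n - 1) + 1):
        loglik, n_params, resp, valid = _fit_mixture_with_noise(x, k, rng)
        bic = -2.0 * loglik + n_params * np.log(n)
        if fallback is None:
            fallback = (bic, k, resp)
        if valid and (best is None or bic < best[0]):
            best = (bic, k, resp)
    bic, k, resp = best if best is not None else fallback
    hard = resp.argmax(axis=1)
    assignments = []
    # renumber non-empty gaussian components 1..K in order of appearance
    label_map: dict[int, int] = {}
    for h in hard:
        if h == k:
            assignments.append("noise")
        else:
            if h not in label_map:
                label_map[h] = len(label_map) + 1
            assignments.append(label_map[h])
    return BioticElementSet(list(species_ids), assignments, x, len(label_map), float(bic))


DEFAULT_SHADE_THRESHOLDS = (0.30, 0.45, 0.60, 1.00)


def element_maps(
    e: BioticElementSet,
    m: IncidenceMatrix,
    thresholds=DEFAULT_SHADE_THRESHOLDS,
) -> dict:
    """Per element and OGU: proportion of element species present and the
    shading class (index of the highest threshold strictly exceeded; the
    top class means every species of the element is present)."""
    thresholds = sorted(thresholds)
    out: dict = {}
    elements = sorted({a for a in e.assignments if a != "noise"}, key=str)
    for el in elements:
        members = e.members(el)
        rows = {}
        for ogu in m.ogu_ids:
            present = sum(1 for s in members if ogu in m.range_of(s))
            proportion = present / len(members) if members else 0.0
            if proportion == 1.0:
                cls = len(thresholds)
            else:
                cls = sum(1 for t in thresholds[:-1] if proportion > t)
            rows[ogu] = {"proportion": proportion, "class": cls}
        out[el] = rows
    return out
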