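"""Jaccard similarity between OGU assemblages and UPGMA dendrograms.

UPGMA is coded directly (rather than delegated) because the phenon-line
machinery needs deterministic, platform-independent tie-breaking: when
several cluster pairs are equidistant the lexicographically smallest pair
of cluster labels merges first, a cluster's label being its smallest leaf
label.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from zooregion.incidence import IncidenceMatrix


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of Jaccard similarity coefficients over OGUs."""

    ogu_ids: list
    values: np.ndarray
    empty_pairs: set = field(default_factory=set)  # pairs with empty union, flagged J=0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ogu_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("similarity values must lie in [0, 1]")

    def value(self, a: str, b: str) -> float:
        i, j = self.ogu_ids.index(a), self.ogu_ids.index(b)
        return float(self.values[i, j])

    def distances(self) -> np.ndarray:
        """Distance matrix D = 1 - J."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def mean_similarity(self, a: str, others) -> float:
        i = self.ogu_ids.index(a)
        idx = [self.ogu_ids.index(o) for o in others]
        return float(self.values[i, idx].mean())

    def write_csv(self, path):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["ogu"] + list(self.ogu_ids))
            for oid, row in zip(self.ogu_ids, self.values):
                w.writerow([oid] + [f"{v:.10g}" for v in row])


def jaccard_similarity(m: IncidenceMatrix) -> SimilarityMatrix:
    """J(u, v) = |A_u & A_v| / |A_u | A_v| over species assemblages.

    Pairs with an empty union (two species-free OGUs) get J = 0 and are
    flagged in ``empty_pairs``.
    """
    if 0 in m.shape:
        raise ValueError("incidence matrix is empty")
    x = m.cells.astype(np.int64)
    inter = x.T @ x
    sizes = x.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    empty = set()
    n = len(m.ogus)
    for a in range(n):
        if sizes[a] == 0:
            j[a, a] = 1.0  # an OGU is identical to itself even when empty
        for b in range(a + 1, n):
            if union[a, b] == 0:
                empty.add((m.ogu_ids[a], m.ogu_ids[b]))
    np.fill_diagonal(j, 1.0)
    return SimilarityMatrix(list(m.ogu_ids), j, empty)


@dataclass
class Merge:
    left: frozenset
    right: frozenset
    height: float

    @property
    def members(self) -> frozenset:
        return self.left | self.right


class Dendrogram:
    """Ultrametric merge tree from average-linkage agglomeration.

    ``merges`` is ordered by merge height; each entry records the two
    clusters joined (as frozensets of leaf labels) and the distance at
    which they joined.  Leaf-to-leaf cophenetic distance is the height of
    the smallest cluster containing both.
    """

    def __init__(self, leaves: list, merges: list[Merge]):
        if len(merges) != len(leaves) - 1:
            raise ValueError("a dendrogram over n leaves needs exactly n-1 merges")
        heights = [m.height for m in merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing (ultrametricity)")
        self.leaves = list(leaves)
        self.merges = list(merges)

    def cophenetic(self) -> np.ndarray:
        n = len(self.leaves)
        idx = {l: i for i, l in enumerate(self.leaves)}
        d = np.zeros((n, n))
        for m in self.merges:
            li = [idx[x] for x in m.left]
            ri = [idx[x] for x in m.right]
            for a in li:
                for b in ri:
                    d[a, b] = d[b, a] = m.height
        return d

    def clusters_at(self, max_height: float) -> list[frozenset]:
        """Partition of leaves into maximal clusters merged at <= max_height."""
        parts = {frozenset([l]) for l in self.leaves}
        for m in self.merges:
            if m.height <= max_height + 1e-12:
                parts.discard(m.left)
                parts.discard(m.right)
                parts.add(m.members)
        return sorted(parts, key=lambda c: sorted(c))

    def subtree_heights(self) -> dict[frozenset, float]:
        """Merge height of every internal cluster (singletons at 0)."""
        h = {frozenset([l]): 0.0 for l in self.leaves}
        for m in self.merges:
            h[m.members] = m.height
        return h

    def to_newick(self, digits: int = 10) -> str:
        """Newick string with ultrametric branch lengths (leaf depth = h/2)."""
        height = {frozenset([l]): 0.0 for l in self.leaves}
        children: dict[frozenset, tuple] = {}
        for m in self.merges:
            height[m.members] = m.height
            children[m.members] = (m.left, m.right)

        def render(cluster: frozenset) -> str:
            if len(cluster) == 1:
                (leaf,) = cluster
                return str(leaf)
            l, r = children[cluster]
            parts = []
            for ch in sorted((l, r), key=lambda c: sorted(c)):
                # every leaf sits at depth height/2 below an ultrametric node
                bl = height[cluster] / 2.0 - height[ch] / 2.0
                parts.append(f"{render(ch)}:{round(bl, digits):.{digits}g}")
            return "(" + ",".join(parts) + ")"

        root = self.merges[-1].members if self.merges else frozenset(self.leaves)
        return render(root) + ";"


def upgma(s: SimilarityMatrix) -> Dendrogram:
    """Average-linkage agglomeration on D = 1 - J.

    At each step the pair at minimal average distance merges; the merged
    cluster's distance to any other is the size-weighted arithmetic mean.
    Ties break on the lexicographically smallest (label_a, label_b) pair,
    a cluster's label being its smallest leaf label.
    """
    n = len(s.ogu_ids)
    if n < 2:
        raise ValueError("need at least two OGUs")
    d = s.distances()
    clusters: dict[int, frozenset] = {i: frozenset([s.ogu_ids[i]]) for i in range(n)}
    labels: dict[int, str] = {i: str(s.ogu_ids[i]) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d[i, j])

    merges: list[Merge] = []
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for (i, j), v in dist.items():
            la, lb = sorted((labels[i], labels[j]))
            key = (v, la, lb)
            if best is None or key < best[0]:
                best = (key, (i, j))
        (v, _, _), (i, j) = best
        a, b = (i, j) if labels[i] <= labels[j] else (j, i)
        merges.append(Merge(clusters[a], clusters[b], v))
        new = next_id
        next_id += 1
        clusters[new] = clusters[i] | clusters[j]
        labels[new] = min(labels[i], labels[j])
        sizes[new] = sizes[i] + sizes[j]
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(new, k), max(new, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        del dist[(min(i, j), max(i, j))]
        active.discard(i)
        active.discard(j)
        active.add(new)

    # enforce exact monotonicity against floating noise
    for k in range(1, len(merges)):
        if merges[k].height < merges[k - 1].height:
            merges[k] = Merge(merges[k].left, merges[k].right, merges[k - 1].height)
    return Dendrogram(list(s.ogu_ids), merges)


def cophenetic(d: Dendrogram) -> SimilarityMatrix:
    """Cophenetic distances packaged with OGU labels (distance, not J)."""
    return SimilarityMatrix(list(d.leaves), d.cophenetic())


def to_newick(d: Dendrogram) -> str:
    return d.to_newick()
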