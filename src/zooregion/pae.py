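"""Parsimony analysis of endemicity (PAE).

OGUs are treated as taxa and species presences as unordered binary
characters.  After pruning constant and singleton characters and empty
OGUs, an all-absent hypothetical root taxon is appended and most
parsimonious trees are sought by random-addition starting trees followed
by tree bisection-reconnection (TBR) branch swapping.  Areas of endemism
(AOEs) are extracted from the strict consensus: geographically contiguous
clades supported by at least two sympatric endemics, plus single OGUs
holding at least two exclusive (singleton) species.

Trees are unrooted and binary, stored as adjacency maps; leaves are taxon
indices, internal nodes have degree three.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from zooregion.incidence import AdjacencyGraph, IncidenceMatrix, PruneReport, prune_matrix

ROOT_TAXON = "ROOT"


@dataclass
class PAEMatrix:
    taxa: list[str]  # OGU ids + ROOT (last)
    characters: list[str]  # species ids
    matrix: np.ndarray  # taxa x characters, binary

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("PAE matrix shape mismatch")

    def to_nexus(self) -> str:
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={len(self.characters)};",
            '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
            "  MATRIX",
        ]
        width = max(len(t) for t in self.taxa) + 2
        for t, row in zip(self.taxa, self.matrix):
            lines.append(f"    {t:<{width}}{''.join(str(int(v)) for v in row)}")
        lines += ["  ;", "END;", ""]
        return "\n".join(lines)


def prepare_pae_matrix(m: IncidenceMatrix) -> tuple[PAEMatrix, PruneReport]:
    """Drop empty OGUs and uninformative characters; append the root taxon.

    Constant characters and single-OGU (singleton) characters are removed;
    singletons are retained in the report for later AOE reconsideration.
    """
    pruned, report = prune_matrix(m, drop_empty_ogus=True, drop_uninformative_species=True)
    if len(pruned.ogus) < 4:
        raise ValueError(
            f"only {len(pruned.ogus)} informative OGUs remain; need at least 4"
        )
    taxa = list(pruned.ogu_ids) + [ROOT_TAXON]
    mat = np.vstack([pruned.cells.T, np.zeros(len(pruned.species), dtype=np.int8)])
    return PAEMatrix(taxa, list(pruned.species_ids), mat), report


# ---------------------------------------------------------------------------
# Unrooted binary trees as adjacency maps
# ---------------------------------------------------------------------------

class Tree:
    """Unrooted binary tree over taxon indices 0..n-1."""

    def __init__(self, n_leaves: int, adj: dict[int, set[int]]):
        self.n_leaves = n_leaves
        self.adj = adj

    @classmethod
    def initial(cls, a: int, b: int, c: int, n_leaves: int) -> "Tree":
        inner = n_leaves
        adj = {a: {inner}, b: {inner}, c: {inner}, inner: {a, b, c}}
        return cls(n_leaves, adj)

    def copy(self) -> "Tree":
        return Tree(self.n_leaves, {k: set(v) for k, v in self.adj.items()})

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (u, v) for u in self.adj for v in self.adj[u] if u < v
        )

    def new_node(self) -> int:
        return max(self.adj) + 1

    def attach_leaf(self, leaf: int, edge: tuple[int, int]) -> "Tree":
        """Return a copy with ``leaf`` attached by subdividing ``edge``."""
        t = self.copy()
        u, v = edge
        w = t.new_node()
        t.adj[u].discard(v)
        t.adj[v].discard(u)
        t.adj[u].add(w)
        t.adj[v].add(w)
        t.adj[w] = {u, v, leaf}
        t.adj[leaf] = {w}
        return t

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the frozenset of leaf indices on the
        side not containing leaf 0."""
        out = set()
        for u, v in self.edges():
            if u < self.n_leaves and v >= self.n_leaves:
                continue  # trivial split (single leaf)
            if v < self.n_leaves and u >= self.n_leaves:
                continue
            if u < self.n_leaves or v < self.n_leaves:
                continue
            side = self._leaves_beyond(u, v)
            if 0 in side:
                side = frozenset(range(self.n_leaves)) - side
            if 1 < len(side):
                out.add(frozenset(side))
        return out

    def _leaves_beyond(self, u: int, v: int) -> frozenset:
        """Leaves in the component containing v after removing edge (u, v)."""
        seen = {u, v}
        stack = [v]
        leaves = []
        while stack:
            x = stack.pop()
            if x < self.n_leaves:
                leaves.append(x)
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(leaves)

    def canonical(self) -> frozenset:
        """Topology fingerprint: the set of non-trivial bipartitions."""
        return frozenset(self.bipartitions())


def fitch_length(tree: Tree, matrix: np.ndarray) -> int:
    """Total Fitch (unordered) steps over all binary characters.

    ``matrix`` is taxa x characters; state sets are bitmasks (1 = state 0,
    2 = state 1) combined leaf-to-root from an arbitrary rooting.
    """
    n = tree.n_leaves
    if n != matrix.shape[0]:
        raise ValueError("tree leaf count does not match matrix taxa")
    masks = np.where(matrix == 1, 2, 1).astype(np.int8)  # taxa x chars
    steps = np.zeros(matrix.shape[1], dtype=np.int64)

    root_leaf = 0
    start = next(iter(tree.adj[root_leaf]))
    # iterative postorder over internal nodes
    order = []
    parent = {start: root_leaf}
    stack = [start]
    while stack:
        x = stack.pop()
        order.append(x)
        for y in tree.adj[x]:
            if y != parent[x]:
                parent[y] = x
                if y >= n:
                    stack.append(y)
    state = {i: masks[i] for i in range(n)}
    for x in reversed(order):
        children = [y for y in tree.adj[x] if y != parent[x]]
        s = state[children[0]]
        for c in children[1:]:
            inter = s & state[c]
            union = s | state[c]
            empty = inter == 0
            steps += empty
            s = np.where(empty, union, inter)
        state[x] = s
    # final union with the root leaf
    inter = state[start] & masks[root_leaf]
    steps += inter == 0
    return int(steps.sum())


def tree_fitch_length(tree: Tree, pm: PAEMatrix) -> int:
    return fitch_length(tree, pm.matrix)


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def random_addition_tree(n_leaves: int, matrix: np.ndarray, rng) -> Tree:
    """Greedy stepwise addition in a random taxon order."""
    order = list(rng.permutation(n_leaves))
    t = Tree.initial(order[0], order[1], order[2], n_leaves)
    for leaf in order[3:]:
        best = None
        for edge in t.edges():
            cand = t.attach_leaf(leaf, edge)
            # score only over taxa already placed: full matrix works because
            # unplaced leaves are absent from the tree
            ln = _partial_length(cand, matrix)
            if best is None or ln < best[0]:
                best = (ln, cand)
        t = best[1]
    return t


def _partial_length(tree: Tree, matrix: np.ndarray) -> int:
    present = sorted(x for x in tree.adj if x < tree.n_leaves)
    if len(present) == tree.n_leaves:
        return fitch_length(tree, matrix)
    remap = {old: new for new, old in enumerate(present)}
    sub_adj: dict[int, set[int]] = {}
    offset = len(present)
    internal_map = {}
    for x in tree.adj:
        if x < tree.n_leaves:
            internal_map[x] = remap[x]
        else:
            internal_map[x] = offset
            offset += 1
    for x, nbrs in tree.adj.items():
        sub_adj[internal_map[x]] = {internal_map[y] for y in nbrs}
    sub = Tree(len(present), sub_adj)
    return fitch_length(sub, matrix[present])


def _suppress_degree_two(adj: dict[int, set[int]], node: int):
    if node in adj and len(adj[node]) == 2:
        a, b = adj[node]
        adj[a].discard(node)
        adj[b].discard(node)
        adj[a].add(b)
        adj[b].add(a)
        del adj[node]


def _components(adj: dict[int, set[int]]) -> list[set[int]]:
    seen: set[int] = set()
    comps = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    stack.append(y)
        seen |= comp
        comps.append(comp)
    return comps


def _tbr_moves(tree: Tree):
    """Yield candidate trees one TBR move away (supersedes SPR/NNI).

    For each edge: bisect, suppress the degree-2 stubs, then reconnect
    every attachment point of one part to every attachment point of the
    other.  Attachment points are edges (subdivided on reattachment), or
    the node itself for a single-leaf part.
    """
    n = tree.n_leaves
    for u, v in tree.edges():
        base = {x: set(s) for x, s in tree.adj.items()}
        base[u].discard(v)
        base[v].discard(u)
        for end in (u, v):
            if end >= n:
                _suppress_degree_two(base, end)
        comps = _components(base)
        if len(comps) != 2:  # pragma: no cover - structural invariant
            raise AssertionError("bisection must yield two components")
        options = []
        for comp in comps:
            if len(comp) == 1:
                options.append([("node", next(iter(comp)))])
            else:
                options.append(
                    [("edge", (a, b)) for a in sorted(comp) for b in sorted(base[a]) if a < b]
                )
        for oa in options[0]:
            for ob in options[1]:
                adj = {x: set(s) for x, s in base.items()}
                nxt = max(adj) + 1
                ends = []
                for kind, val in (oa, ob):
                    if kind == "node":
                        ends.append(val)
                    else:
                        a, b = val
                        w = nxt
                        nxt += 1
                        adj[a].discard(b)
                        adj[b].discard(a)
                        adj[a].add(w)
                        adj[b].add(w)
                        adj[w] = {a, b}
                        ends.append(w)
                pa, pb = ends
                adj[pa].add(pb)
                adj[pb].add(pa)
                yield Tree(n, adj)


@dataclass
class SearchResult:
    best_length: int
    trees: list[Tree] = field(default_factory=list)

    @property
    def topologies(self) -> set[frozenset]:
        return {t.canonical() for t in self.trees}


def heuristic_search(
    pm: PAEMatrix,
    n_replicates: int = 10,
    seed: int = 0,
    max_trees: int = 1000,
) -> SearchResult:
    """Random-addition + TBR hill climbing, pooling equally best trees.

    Deterministic for a given seed.  The pool is capped at ``max_trees``
    distinct topologies.
    """
    matrix = pm.matrix
    n = len(pm.taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    best_length = None
    pool: dict[frozenset, Tree] = {}
    for _ in range(n_replicates):
        t = random_addition_tree(n, matrix, rng)
        ln = fitch_length(t, matrix)
        improved = True
        while improved:
            improved = False
            for cand in _tbr_moves(t):
                cl = fitch_length(cand, matrix)
                if cl < ln:
                    t, ln = cand, cl
                    improved = True
                    break
        if best_length is None or ln < best_length:
            best_length = ln
            pool = {t.canonical(): t}
        elif ln == best_length and len(pool) < max_trees:
            pool.setdefault(t.canonical(), t)
        # sweep the local plateau: collect equally-parsimonious neighbours
        if ln == best_length:
            for cand in _tbr_moves(t):
                if len(pool) >= max_trees:
                    break
                if fitch_length(cand, matrix) == best_length:
                    pool.setdefault(cand.canonical(), cand)
    return SearchResult(best_length, list(pool.values()))


def exhaustive_search(pm: PAEMatrix) -> SearchResult:
    """Enumerate every unrooted topology (feasible for <= ~9 taxa)."""
    matrix = pm.matrix
    n = len(pm.taxa)
    best = None
    trees: dict[frozenset, Tree] = {}

    def grow(t: Tree, leaf: int):
        nonlocal best, trees
        if leaf == n:
            ln = fitch_length(t, matrix)
            if best is None or ln < best:
                best = ln
                trees = {t.canonical(): t}
            elif ln == best:
                trees.setdefault(t.canonical(), t)
            return
        for edge in t.edges():
            grow(t.attach_leaf(leaf, edge), leaf + 1)

    grow(Tree.initial(0, 1, 2, n), 3)
    return SearchResult(best, list(trees.values()))


# ---------------------------------------------------------------------------
# Consensus and AOEs
# ---------------------------------------------------------------------------

def strict_consensus(trees: list[Tree]) -> set[frozenset]:
    """Bipartitions present in every input tree (leaf sets must agree)."""
    if not trees:
        raise ValueError("no trees")
    n = trees[0].n_leaves
    if any(t.n_leaves != n for t in trees):
        raise ValueError("leaf-set mismatch across trees")
    common = trees[0].bipartitions()
    for t in trees[1:]:
        common &= t.bipartitions()
    return common


def consensus_clades(bipartitions: set[frozenset], taxa: list[str]) -> list[frozenset]:
    """Turn root-free splits into clades of OGU ids, rooted on ROOT.

    The side of each split not containing the root taxon is a clade.
    """
    try:
        root_idx = taxa.index(ROOT_TAXON)
    except ValueError:
        root_idx = None
    clades = []
    all_idx = frozenset(range(len(taxa)))
    for side in bipartitions:
        if root_idx is not None and root_idx in side:
            side = all_idx - side
        clades.append(frozenset(taxa[i] for i in side if taxa[i] != ROOT_TAXON))
    return sorted(set(clades), key=lambda c: (len(c), sorted(c)))


def consensus_to_newick(bipartitions: set[frozenset], taxa: list[str]) -> str:
    """Render the (possibly unresolved) strict consensus rooted on ROOT."""
    clades = consensus_clades(bipartitions, taxa)
    universe = frozenset(t for t in taxa if t != ROOT_TAXON)
    clades = [c for c in clades if c != universe]

    def render(node: frozenset, pool: list[frozenset]) -> str:
        direct = [c for c in pool if c < node and not any(c < d < node for d in pool)]
        covered = set().union(*direct) if direct else set()
        parts = [render(c, pool) for c in sorted(direct, key=lambda x: sorted(x))]
        parts += sorted(node - covered)
        return "(" + ",".join(parts) + ")"

    body = render(universe, clades)
    return f"({ROOT_TAXON},{body});"


@dataclass
class AOE:
    members: frozenset
    supporting_species: list
    provenance: str  # consensus_clade | singleton_ogu


def extract_aoes(
    bipartitions: set[frozenset],
    taxa: list[str],
    m: IncidenceMatrix,
    g: AdjacencyGraph,
    singleton_report: dict[str, str] | None = None,
    min_support: int = 2,
) -> list[AOE]:
    """AOEs from consensus clades plus singleton OGUs.

    A clade qualifies when it is contiguous on the adjacency graph and at
    least ``min_support`` species are endemic to it with at least one
    sympatric pair (co-occurring in a member OGU).  A single OGU holding
    >= ``min_support`` species found nowhere else qualifies as a singleton
    AOE unless already inside a clade AOE.
    """
    aoes: list[AOE] = []
    for clade in consensus_clades(bipartitions, taxa):
        if len(clade) < 2 or not g.is_contiguous(clade):
            continue
        endemics = [
            sid for sid in m.species_ids if m.range_of(sid) and m.range_of(sid) <= clade
        ]
        if len(endemics) < min_support:
            continue
        sympatric = any(
            m.range_of(a) & m.range_of(b)
            for a, b in itertools.combinations(endemics, 2)
        )
        if sympatric:
            aoes.append(AOE(frozenset(clade), sorted(endemics), "consensus_clade"))
    taken = set().union(*(a.members for a in aoes)) if aoes else set()
    singles: dict[str, list] = {}
    for sid, ogu in (singleton_report or {}).items():
        singles.setdefault(ogu, []).append(sid)
    # species that were never pruned but still occupy a single OGU count too
    for sid in m.species_ids:
        rng = m.range_of(sid)
        if len(rng) == 1:
            (ogu,) = rng
            if sid not in singles.get(ogu, []):
                singles.setdefault(ogu, []).append(sid)
    for ogu, sids in sorted(singles.items()):
        if ogu in taken:
            continue
        if len(sids) >= min_support:
            aoes.append(AOE(frozenset([ogu]), sorted(sids), "singleton_ogu"))
    return aoes


def write_aoe_tsv(aoes: list[AOE], path):
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["members", "n_supporting", "supporting_species", "provenance"])
        for a in aoes:
            w.writerow(
                [" ".join(sorted(a.members)), len(a.supporting_species),
                 " ".join(a.supporting_species), a.provenance]
            )
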