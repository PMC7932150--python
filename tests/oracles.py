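"""Independent brute-force oracles used to verify the package's algorithms.

Deliberately naive formulations, coded apart from the package:

- average linkage defined directly as the mean over all original leaf-pair
  distances (not the Lance-Williams update the package uses);
- parsimony length by recursive set-based Fitch over exhaustively
  enumerated unrooted topologies;
- Jenks as exhaustive search over contiguous partitions of the sorted
  values.
"""

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Naive UPGMA: cluster distance = mean over all original leaf pairs
# ---------------------------------------------------------------------------

def naive_average_linkage(labels, dmat):
    """Return merges [(left frozenset, right frozenset, height)] using the
    textbook definition of average linkage, with ties broken by the
    lexicographically smallest (min-leaf-label, min-leaf-label) pair."""
    dmat = np.asarray(dmat, dtype=float)
    index = {l: i for i, l in enumerate(labels)}
    clusters = [frozenset([l]) for l in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = float(
                np.mean([dmat[index[x], index[y]] for x in a for y in b])
            )
            la, lb = sorted((min(a), min(b)))
            key = (d, str(la), str(lb))
            if best is None or key < best[0]:
                pair = (a, b) if min(a) <= min(b) else (b, a)
                best = (key, pair)
        (d, _, _), (a, b) = best
        merges.append((a, b, d))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


# ---------------------------------------------------------------------------
# Exhaustive parsimony
# ---------------------------------------------------------------------------

def _enumerate_unrooted(n):
    """All unrooted binary topologies over leaves 0..n-1 as edge lists;
    internal nodes are negative ints."""
    assert n >= 3
    base = [(-1, 0), (-1, 1), (-1, 2)]
    trees = [base]
    for leaf in range(3, n):
        new_trees = []
        inner = -(leaf - 1)
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                e2 = edges[:i] + edges[i + 1:]
                new_trees.append(e2 + [(u, inner), (inner, v), (inner, leaf)])
        trees = new_trees
    return trees


def _fitch_steps_edges(edges, char):
    """Fitch steps for one binary character (list per leaf) on an edge list."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def down(node, parent):
        if node >= 0:
            return {char[node]}, 0
        state, steps = None, 0
        for ch in adj[node]:
            if ch == parent:
                continue
            cs, cst = down(ch, node)
            steps += cst
            if state is None:
                state = cs
            else:
                inter = state & cs
                if inter:
                    state = inter
                else:
                    state = state | cs
                    steps += 1
        return state, steps

    root = 0  # root on leaf 0
    child = adj[root][0]
    cs, steps = down(child, root)
    if char[root] not in cs:
        steps += 1
    return steps


def exhaustive_parsimony_min(matrix):
    """Minimum parsimony length over all unrooted topologies.

    ``matrix`` is taxa x characters (0/1).  Feasible up to ~8 taxa.
    """
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    best = None
    for edges in _enumerate_unrooted(n):
        total = 0
        for j in range(matrix.shape[1]):
            total += _fitch_steps_edges(edges, list(matrix[:, j]))
        if best is None or total < best:
            best = total
    return best


# ---------------------------------------------------------------------------
# Exhaustive Jenks
# ---------------------------------------------------------------------------

def exhaustive_jenks_min_ssd(values, k):
    """Minimum within-class SSD over all contiguous partitions of the
    sorted values into k non-empty classes."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def ssd(seg):
        return float(((seg - seg.mean()) ** 2).sum())

    best = None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        total = sum(ssd(v[a:b]) for a, b in zip(bounds, bounds[1:]))
        if best is None or total < best:
            best = total
    return best
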