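"""Pairwise dissimilarities, UPGMA tree construction, clusters, Newick export.

The dissimilarity value (DV) between two sequences is the Euclidean
distance between their PC-score rows.  The m(m-1)/2 distances are kept in
the condensed pair order (2,1), (3,1), ..., (m,1), (3,2), ..., (m,m-1).
UPGMA merges the closest pair at half its dissimilarity and updates
inter-cluster distances as the size-weighted arithmetic mean over all
cross-cluster pairs, yielding a rooted ultrametric tree.  Genetic distance
(GD) between two taxa is the cophenetic distance on that tree: twice the
height of their lowest common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

#: Distances within this of the running minimum are treated as exact ties.
TIE_GUARD = 1e-12


@dataclass
class CondensedDistances:
    """Length-m(m-1)/2 vector of pairwise dissimilarities in (2,1),(3,1),... order."""

    values: np.ndarray
    ids: list[str]

    @property
    def m(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DissimilarityMatrix:
    """Symmetric m x m dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    ids: list[str]

    @property
    def m(self) -> int:
        return len(self.ids)


@dataclass
class UPGMATree:
    """Rooted ultrametric tree from agglomerative average-linkage merges.

    ``merges`` has one row per internal node: (left, right, height, size),
    where leaves are numbered 0..m-1 in ``leaves`` order and internal node t
    gets id m + t.  Heights are in DV units; root height is the last merge's.
    """

    merges: np.ndarray  # (m-1, 4) float
    leaves: list[str]

    @property
    def m(self) -> int:
        return len(self.leaves)

    @property
    def root_height(self) -> float:
        return float(self.merges[-1, 2]) if len(self.merges) else 0.0


@dataclass
class ClusterAssignment:
    """Mapping taxon id -> cluster index (contiguous, starting at 1)."""

    labels: dict[str, int]
    n_clusters: int


def pairwise_euclidean_condensed(S) -> CondensedDistances:
    """Euclidean distances between score rows, condensed pair order."""
    X = np.asarray(S.scores, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 score rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("scores contain non-finite values")
    return CondensedDistances(values=pdist(X, metric="euclidean"), ids=list(S.row_ids))


def to_square(d: CondensedDistances) -> DissimilarityMatrix:
    """Expand a condensed vector into the full symmetric zero-diagonal matrix."""
    n_vals = len(d.values)
    if n_vals != d.m * (d.m - 1) // 2:
        raise ValueError(
            f"condensed length {n_vals} is not m(m-1)/2 for m={d.m} taxa"
        )
    if d.m == 1:
        return DissimilarityMatrix(values=np.zeros((1, 1)), ids=list(d.ids))
    return DissimilarityMatrix(values=squareform(d.values), ids=list(d.ids))


def condense(dm: DissimilarityMatrix) -> CondensedDistances:
    """Inverse of :func:`to_square`."""
    if dm.m == 1:
        return CondensedDistances(values=np.zeros(0), ids=list(dm.ids))
    return CondensedDistances(values=squareform(dm.values, checks=False), ids=list(dm.ids))


def _check_dissimilarity(values: np.ndarray) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(values, values.T, rtol=0, atol=0):
        raise ValueError("dissimilarity matrix must be exactly symmetric")
    if np.any(values < 0):
        raise ValueError("dissimilarity matrix has negative entries")
    if np.any(np.diag(values) != 0):
        raise ValueError("dissimilarity matrix diagonal must be zero")


def upgma(dm: DissimilarityMatrix) -> UPGMATree:
    """Build the UPGMA tree by iterative closest-pair merging.

    Each step merges the minimum-distance active pair at height d_min / 2
    and replaces the pair by their union, with distances to every other
    cluster updated as (n_a * d_a + n_b * d_b) / (n_a + n_b) — the
    arithmetic mean over all cross-cluster leaf pairs.  Ties within 1e-12
    resolve to the lowest (row, column) cluster-id pair, so output is
    deterministic.
    """
    values = np.asarray(dm.values, dtype=float)
    _check_dissimilarity(values)
    m = values.shape[0]
    if m < 2:
        raise ValueError("need at least 2 taxa")

    dist = {}  # (low_id, high_id) -> distance, over active cluster ids
    for i in range(m):
        for j in range(i + 1, m):
            dist[(i, j)] = values[i, j]
    size = {i: 1 for i in range(m)}
    active = list(range(m))
    merges = np.zeros((m - 1, 4), dtype=float)

    for t in range(m - 1):
        d_min = min(dist[(a, b)] for idx, a in enumerate(active) for b in active[idx + 1 :])
        best = None
        for idx, a in enumerate(active):
            for b in active[idx + 1 :]:
                if dist[(a, b)] <= d_min + TIE_GUARD and best is None:
                    best = (a, b)
        a, b = best
        new_id = m + t
        merges[t] = (a, b, dist[(a, b)] / 2.0, size[a] + size[b])
        for c in active:
            if c in (a, b):
                continue
            d_ac = dist[(min(a, c), max(a, c))]
            d_bc = dist[(min(b, c), max(b, c))]
            dist[(c, new_id)] = (size[a] * d_ac + size[b] * d_bc) / (size[a] + size[b])
        size[new_id] = size[a] + size[b]
        active = [c for c in active if c not in (a, b)] + [new_id]

    return UPGMATree(merges=merges, leaves=list(dm.ids))


def _leaf_sets(tree: UPGMATree) -> list[set[int]]:
    """Leaf index set under each node (leaves first, then internal nodes)."""
    m = tree.m
    sets: list[set[int]] = [{i} for i in range(m)]
    for left, right, _h, _s in tree.merges:
        sets.append(sets[int(left)] | sets[int(right)])
    return sets


def _node_heights(tree: UPGMATree) -> np.ndarray:
    heights = np.zeros(2 * tree.m - 1)
    heights[tree.m :] = tree.merges[:, 2]
    return heights


def cophenetic_distance(tree: UPGMATree, i: str, j: str) -> float:
    """Tree distance between two taxa: twice the height of their LCA."""
    try:
        ii, jj = tree.leaves.index(i), tree.leaves.index(j)
    except ValueError as exc:
        raise ValueError(f"taxon not in tree: {exc}") from None
    if ii == jj:
        return 0.0
    sets = _leaf_sets(tree)
    for t, (_l, _r, h, _s) in enumerate(tree.merges):
        if {ii, jj} <= sets[tree.m + t]:
            return 2.0 * float(h)
    raise AssertionError("tree has no root covering both taxa")  # pragma: no cover


def cut_tree(tree: UPGMATree, k: int) -> ClusterAssignment:
    """Cut away the k-1 highest merges, leaving k connected groups.

    Merges are applied in height order (the construction order), so keeping
    the first m-k merges yields the k clusters.  Cluster indices are
    assigned 1..k by first appearance in leaf order.
    """
    m = tree.m
    if not 1 <= k <= m:
        raise ValueError(f"k={k} out of range 1..{m}")
    parent = list(range(2 * m - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(m - k):
        left, right, _h, _s = tree.merges[t]
        node = m + t
        parent[find(int(left))] = node
        parent[find(int(right))] = node

    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for idx, name in enumerate(tree.leaves):
        root = find(idx)
        if root not in roots:
            roots[root] = len(roots) + 1
        labels[name] = roots[root]
    return ClusterAssignment(labels=labels, n_clusters=len(roots))


def write_newick(tree: UPGMATree) -> str:
    """Serialize the tree as rooted Newick with branch lengths in DV units.

    Every leaf-to-root path sums to the root height (ultrametricity is
    preserved exactly in the branch lengths, up to print precision).
    Children are ordered by the smallest leaf index in their subtree, so
    output is deterministic regardless of merge orientation.
    """
    heights = _node_heights(tree)
    sets = _leaf_sets(tree)

    def render(node: int) -> str:
        if node < tree.m:
            return tree.leaves[node]
        left, right, _h, _s = tree.merges[node - tree.m]
        children = sorted((int(left), int(right)), key=lambda c: min(sets[c]))
        parts = []
        for child in children:
            blen = heights[node] - heights[child]
            parts.append(f"{render(child)}:{blen:.12g}")
        return "(" + ",".join(parts) + ")"

    return render(2 * tree.m - 2) + ";"
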