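"""Complete-linkage hierarchical clustering of occupancy profiles.

Both the particle classes (columns) and the structural features (rows)
of an occupancy matrix are clustered agglomeratively with the
Euclidean metric and complete linkage (inter-cluster distance = the
maximum pairwise member distance), mirroring the standard
`scipy.cluster.hierarchy.linkage(..., method="complete")` semantics.

The agglomerator is written out explicitly here so its tie-breaking
rule is part of the contract: at every step the minimum-distance pair
merges, and ties resolve to the smallest (left, right) node-index pair
lexicographically.  Library implementations leave tie order
unspecified, which is not acceptable for bit-reproducible pipelines;
scipy serves as an independent cross-check in the test suite instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ParameterError
from .occupancy import OccupancyMatrix

__all__ = [
    "LinkageTree",
    "euclidean_distances",
    "complete_linkage",
    "cut_tree",
    "to_newick",
]


@dataclass
class LinkageTree:
    """Agglomeration record: n-1 merges over n leaves.

    Node ids: leaves are 0..n-1 in ``leaf_ids`` order; the merge at
    step s creates node n+s.  ``merges`` rows are (left, right, height,
    member_count) with non-decreasing heights (complete linkage is
    monotone).
    """

    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ParameterError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def root_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix in scipy's (left, right, height, count) layout."""
        return np.array([[l, r, h, c] for l, r, h, c in self.merges], dtype=float)


def euclidean_distances(m: OccupancyMatrix, axis: str = "columns") -> np.ndarray:
    """Pairwise Euclidean distances between rows or columns.

    Returns the full symmetric matrix (zero diagonal).  ``axis`` names
    the items being compared: ``"columns"`` clusters classes over their
    feature profiles, ``"rows"`` clusters features over classes.
    """
    if axis == "columns":
        items = m.values.T
    elif axis == "rows":
        items = m.values
    else:
        raise ParameterError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if items.shape[0] < 2:
        raise ParameterError(f"need >= 2 items along {axis}, got {items.shape[0]}")
    return squareform(pdist(items, metric="euclidean"))


def complete_linkage(distances: np.ndarray, leaf_ids=None) -> LinkageTree:
    """Agglomerate by complete linkage with lexicographic tie-breaking.

    ``distances`` is a full symmetric matrix.  At every step the
    minimum-distance cluster pair merges; the inter-cluster distance is
    the maximum pairwise member distance, updated by the max rule.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ParameterError("distance table must be square")
    n = d.shape[0]
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    if len(leaf_ids) != n:
        raise ParameterError("leaf_ids length mismatch")
    # active clusters: node id -> current distance row index
    dist: dict[tuple[int, int], float] = {}
    active: list[int] = list(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best_pair = None
        best_d = np.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                key = (a, b) if a < b else (b, a)
                dd = dist[key]
                if dd < best_d or (dd == best_d and (best_pair is None or key < best_pair)):
                    best_d = dd
                    best_pair = key
        a, b = best_pair
        new = next_id
        next_id += 1
        sizes[new] = sizes[a] + sizes[b]
        merges.append((a, b, float(best_d), sizes[new]))
        active = [x for x in active if x not in (a, b)]
        for c in active:
            ka = (a, c) if a < c else (c, a)
            kb = (b, c) if b < c else (c, b)
            dist[(c, new)] = max(dist[ka], dist[kb])
        active.append(new)
    return LinkageTree(merges, list(leaf_ids))


def cut_tree(tree: LinkageTree, k: int) -> dict[str, int]:
    """Partition leaves into k groups by removing the k-1 highest merges.

    Heights are non-decreasing along the merge order, so dropping the
    last k-1 merges and taking connected components is deterministic.
    Group indices are assigned in leaf order (group of the first leaf
    is 0, the next unseen group 1, ...).
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (left, right, _h, _c) in enumerate(tree.merges[: n - k]):
        new = n + step
        parent[find(left)] = new
        parent[find(right)] = new
    groups: dict[str, int] = {}
    relabel: dict[int, int] = {}
    for leaf, leaf_id in enumerate(tree.leaf_ids):
        root = find(leaf)
        if root not in relabel:
            relabel[root] = len(relabel)
        groups[leaf_id] = relabel[root]
    return groups


def to_newick(tree: LinkageTree) -> str:
    """Ultrametric Newick serialization.

    Every leaf sits at depth ``root_height / 2``, so the path length
    between two leaves equals their merge height — i.e. branch lengths
    encode the cophenetic distance directly.
    """
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for step, (left, right, h, _c) in enumerate(tree.merges):
        node = n + step
        heights[node] = h
        children[node] = (left, right)

    def render(node: int) -> str:
        if node < n:
            return _escape(tree.leaf_ids[node])
        left, right = children[node]
        parts = []
        for child in (left, right):
            blen = (heights[node] - heights[child]) / 2.0
            parts.append(f"{render(child)}:{blen:.10g}")
        return "(" + ",".join(parts) + ")"

    if n == 1:
        return _escape(tree.leaf_ids[0]) + ";"
    return render(n + len(tree.merges) - 1) + ";"


def _escape(label: str) -> str:
    if any(c in label for c in " (),:;'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label
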