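"""Ward hierarchical clustering of duplicate pairs and tree cuts into functional groups.

Similarities become distances via d = 1 - s.  Ward's method is run through the
Lance-Williams recursion on squared dissimilarities; recorded merge heights are
the Ward merge cost (the within-group sum-of-squares increase), so two
singletons at distance d merge at height d^2/2.

Two cuts are provided: the minimum-size rule — every leaf joins its lowest
ancestor holding at least ``min_size`` leaves, undersized candidate groups are
merged upward — and a fixed-height cut for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .semsim import ProfileSimilarityMatrix

logger = logging.getLogger(__name__)


class ClusterError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ClusterError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(v)):
            raise ClusterError("distance matrix contains non-finite entries")
        if np.abs(v - v.T).max(initial=0.0) > 1e-9:
            raise ClusterError("distance matrix is asymmetric beyond tolerance")


def similarity_to_distance(matrix: ProfileSimilarityMatrix) -> DistanceMatrix:
    """d(i, j) = 1 - s(i, j); the unit diagonal maps to exact zeros."""
    s = matrix.values
    if np.abs(s - s.T).max(initial=0.0) > 1e-9:
        raise ClusterError("similarity matrix is asymmetric beyond tolerance")
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(matrix.pair_ids), values=d)


@dataclass
class Dendrogram:
    """Binary merge tree over leaves; ``heights`` are Ward merge costs.

    ``merges[i] = (a, b)`` joins nodes a and b (leaves are 0..n-1, internal
    node i is n+i) at height ``heights[i]``.
    """

    leaves: list[str]
    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) Ward merge cost
    scipy_linkage: np.ndarray  # raw linkage matrix, distance-scale heights

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_counts(self) -> np.ndarray:
        n = self.n_leaves
        counts = np.ones(2 * n - 1, dtype=int)
        for i, (a, b) in enumerate(self.merges):
            counts[n + i] = counts[a] + counts[b]
        return counts

    def parents(self) -> np.ndarray:
        n = self.n_leaves
        par = np.full(2 * n - 1, -1, dtype=int)
        for i, (a, b) in enumerate(self.merges):
            par[a] = par[b] = n + i
        return par

    def subtree_leaves(self, node: int) -> list[int]:
        n = self.n_leaves
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend(self.merges[v - n])
        return sorted(out)

    def to_newick(self) -> str:
        n = self.n_leaves
        heights = np.concatenate([np.zeros(n), self.heights])

        def render(node: int) -> str:
            if node < n:
                return self.leaves[node]
            a, b = self.merges[node - n]
            h = heights[node]
            parts = ",".join(
                f"{render(c)}:{max(h - heights[c], 0.0):.10g}" for c in (a, b)
            )
            return f"({parts})"

        return render(2 * n - 2) + ";"


def ward_linkage(d: DistanceMatrix) -> Dendrogram:
    """Agglomerate by Ward's criterion with deterministic merge ordering."""
    n = len(d.ids)
    if n < 2:
        raise ClusterError("ward_linkage requires at least 2 leaves")
    z = linkage(squareform(d.values, checks=False), method="ward")
    return Dendrogram(
        leaves=list(d.ids),
        merges=z[:, :2].astype(int),
        heights=z[:, 2] ** 2 / 2.0,
        scipy_linkage=z,
    )


@dataclass(frozen=True)
class FunctionalGroup:
    group_id: str
    members: tuple[str, ...]
    height: float
    namespace: str | None = None


def _as_groups(
    assignments: dict[int, list[int]], tree: Dendrogram, namespace: str | None
) -> list[FunctionalGroup]:
    n = tree.n_leaves
    heights = np.concatenate([np.zeros(n), tree.heights])
    groups = []
    for rank, node in enumerate(sorted(assignments), start=1):
        members = tuple(tree.leaves[i] for i in sorted(assignments[node]))
        groups.append(
            FunctionalGroup(
                group_id=f"G{rank:02d}",
                members=members,
                height=float(heights[node]),
                namespace=namespace,
            )
        )
    return groups


def cut_by_min_size(
    tree: Dendrogram, min_size: int = 20, namespace: str | None = None
) -> list[FunctionalGroup]:
    """Partition leaves by the lowest-ancestor-with->=min_size rule.

    Each leaf is claimed by its lowest (possibly itself) ancestor holding at
    least ``min_size`` leaves; leaves claimed by the same node form a candidate
    group.  Candidates below ``min_size`` (leaves whose qualifying node also
    has a qualifying child that claimed the rest) are merged upward into the
    next qualifying ancestor's candidate; a residual left at the root is
    absorbed into the deepest emitted group, so the output partitions the
    leaves with every group >= min_size.
    """
    if min_size < 1:
        raise ClusterError("min_size must be >= 1")
    n = tree.n_leaves
    if min_size > n:
        logger.warning(
            "min_size %d exceeds leaf count %d; returning a single root group",
            min_size,
            n,
        )
        return _as_groups({2 * n - 2: list(range(n))}, tree, namespace)
    counts = tree.leaf_counts()
    parent = tree.parents()
    qualifying = counts >= min_size

    assignments: dict[int, list[int]] = {}
    for leaf in range(n):
        node = leaf
        while not qualifying[node]:
            node = parent[node]
        assignments.setdefault(node, []).append(leaf)

    # merge undersized candidates upward, bottom-up (node index = merge order;
    # merge targets always carry a larger index, so one ascending sweep suffices)
    for node in range(2 * n - 1):
        if node not in assignments:
            continue
        members = assignments[node]
        if len(members) >= min_size or parent[node] == -1:
            continue
        anc = parent[node]
        while not qualifying[anc]:
            anc = parent[anc]
        assignments.setdefault(anc, []).extend(members)
        del assignments[node]

    root = 2 * n - 2
    residual = assignments.get(root)
    if residual is not None and len(residual) < min_size and len(assignments) > 1:
        heights = np.concatenate([np.zeros(n), tree.heights])
        others = [v for v in assignments if v != root]
        target = max(others, key=lambda v: (heights[v], v))
        assignments[target].extend(residual)
        del assignments[root]
    return _as_groups(assignments, tree, namespace)


def cut_by_height(
    tree: Dendrogram, h: float, namespace: str | None = None
) -> list[FunctionalGroup]:
    """Maximal subtrees whose merge height (Ward cost) is <= h; singletons allowed."""
    if h < 0:
        raise ClusterError("cut height must be >= 0")
    # Ward costs are scipy heights^2 / 2 and the transform is monotone
    labels = fcluster(tree.scipy_linkage, t=np.sqrt(2.0 * h), criterion="distance")
    parent = tree.parents()
    by_label: dict[int, list[int]] = {}
    for leaf, lab in enumerate(labels):
        by_label.setdefault(int(lab), []).append(leaf)
    # the defining node of a cluster is its highest ancestor whose subtree
    # stays inside the cluster
    assignments: dict[int, list[int]] = {}
    for leaves in by_label.values():
        leafset = set(leaves)
        node = leaves[0]
        while parent[node] != -1 and set(tree.subtree_leaves(parent[node])) <= leafset:
            node = parent[node]
        assignments[node] = leaves
    return _as_groups(assignments, tree, namespace)
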