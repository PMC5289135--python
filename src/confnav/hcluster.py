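"""Agglomerative clustering under the RMS linkage, with representatives.

The linkage distance between two clusters X and Y is the root-mean-square of
all cross-cluster pairwise distances,

    Δ(X, Y) = sqrt( 1/(N_X N_Y) Σ_{x∈X, y∈Y} D²(x, y) ) ,

which admits an exact Lance–Williams-style update under merging:

    Δ²(X∪Y, Z) = (N_X Δ²(X, Z) + N_Y Δ²(Y, Z)) / (N_X + N_Y) .

Each cluster can be summarized by its representative structure — the member
with minimum mean squared distance to all members — and by its spread σ_D,
the RMS distance of the members to the representative.

RMS linkage is not guaranteed monotone; height inversions are recorded as
computed and counted in the log rather than adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .rematch import DistanceMatrix

__all__ = [
    "Merge",
    "ClusterTree",
    "Cluster",
    "linkage",
    "cut",
    "representative",
    "spread",
    "suggest_cut_height",
    "RMSLinkageClustering",
    "linkage_table",
    "to_newick",
    "plot_dendrogram",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Merge:
    """One agglomeration: nodes joined, linkage height Δ, merged size."""

    left: int
    right: int
    height: float
    count: int


@dataclass
class ClusterTree:
    """Sequence of N−1 merges over leaves 0..N−1 (internal nodes N..2N−2)."""

    merges: list[Merge]
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        if self.merges and self.merges[-1].count != n:
            raise ValueError("final merge must contain all leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def children(self, node: int) -> tuple[int, int]:
        m = self.merges[node - self.n_leaves]
        return m.left, m.right

    def leaves_of(self, node: int) -> list[int]:
        """Leaf indices under a node, in left-to-right dendrogram order."""
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                l, r = self.children(v)
                stack.extend((r, l))
        return out

    def subtree_max_height(self) -> np.ndarray:
        """Max merge height within each internal node's subtree."""
        n = self.n_leaves
        out = np.zeros(len(self.merges))
        for t, m in enumerate(self.merges):
            h = m.height
            for child in (m.left, m.right):
                if child >= n:
                    h = max(h, out[child - n])
            out[t] = h
        return out

    def n_inversions(self) -> int:
        """Merges whose height is below an earlier merge in their own subtree."""
        n = self.n_leaves
        sub = self.subtree_max_height()
        return int(
            sum(
                1
                for t, m in enumerate(self.merges)
                if any(
                    child >= n and sub[child - n] > m.height + 1e-15
                    for child in (m.left, m.right)
                )
            )
        )


@dataclass
class Cluster:
    """A flat cluster: members, representative and spreads (when computed)."""

    member_ids: list[str]
    member_indices: list[int] = field(default_factory=list)
    representative_id: str | None = None
    spread: float | None = None
    property_spread: float | None = None

    def __len__(self) -> int:
        return len(self.member_ids)


def _as_matrix(D: DistanceMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, DistanceMatrix):
        ids = D.ids if D.ids else [str(i) for i in range(len(D.values))]
        return D.values, ids
    Dv = np.asarray(D, dtype=float)
    if Dv.ndim != 2 or Dv.shape[0] != Dv.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(Dv - Dv.T).max() > 1e-10:
        raise ValueError("distance matrix must be symmetric")
    if Dv.min() < 0:
        raise ValueError("distances must be non-negative")
    return Dv, [str(i) for i in range(Dv.shape[0])]


def linkage(D: DistanceMatrix | np.ndarray) -> ClusterTree:
    """Agglomerate singletons under RMS linkage.

    Ties on equal Δ are broken by the lexicographically smallest
    (left, right) node-index pair, making the merge sequence deterministic.
    """
    Dv, ids = _as_matrix(D)
    n = Dv.shape[0]
    if n < 2:
        raise ValueError("need at least 2 structures to cluster")
    total = 2 * n - 1
    # delta2[a, b] = Δ²(cluster a, cluster b) for active nodes a < b
    delta2 = np.full((total, total), np.inf)
    delta2[:n, :n] = Dv**2
    iu = np.tril_indices(n)
    delta2[:n, :n][iu] = np.inf  # keep upper triangle only
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    merges: list[Merge] = []
    for step in range(n - 1):
        flat = int(np.argmin(delta2))  # row-major: lexicographic tie-break
        a, b = divmod(flat, total)
        if not np.isfinite(delta2[a, b]):
            raise RuntimeError("no finite linkage found (corrupt matrix?)")
        new = n + step
        na, nb = sizes[a], sizes[b]
        merges.append(Merge(a, b, float(np.sqrt(delta2[a, b])), int(na + nb)))
        # Lance-Williams update, exact for RMS linkage
        act = np.where(active)[0]
        act = act[(act != a) & (act != b)]
        d2a = np.where(act < a, delta2[act, a], delta2[a, act])
        d2b = np.where(act < b, delta2[act, b], delta2[b, act])
        delta2[act, new] = (na * d2a + nb * d2b) / (na + nb)
        # retire a and b
        delta2[a, :] = np.inf
        delta2[:, a] = np.inf
        delta2[b, :] = np.inf
        delta2[:, b] = np.inf
        active[a] = active[b] = False
        active[new] = True
        sizes[new] = na + nb
    tree = ClusterTree(merges, ids)
    ninv = tree.n_inversions()
    if ninv:
        logger.info("RMS linkage produced %d height inversion(s)", ninv)
    return tree


def cut(tree: ClusterTree, height: float) -> list[Cluster]:
    """Flat clusters: maximal subtrees whose internal merges all have Δ ≤ height.

    Every leaf belongs to exactly one cluster; with inversions possible, a
    subtree qualifies on its *maximum* internal height, not just its root's.
    """
    if height < 0:
        raise ValueError("height must be >= 0")
    n = tree.n_leaves
    sub = tree.subtree_max_height()
    clusters: list[Cluster] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node < n:
            clusters.append(Cluster([tree.leaf_ids[node]], [node]))
        elif sub[node - n] <= height:
            leaves = tree.leaves_of(node)
            clusters.append(Cluster([tree.leaf_ids[i] for i in leaves], leaves))
        else:
            l, r = tree.children(node)
            stack.extend((r, l))
    clusters.sort(key=lambda c: min(c.member_indices))
    return clusters


def _indices(members: Sequence[str | int], ids: list[str]) -> list[int]:
    idx: list[int] = []
    lookup = {sid: i for i, sid in enumerate(ids)}
    for m in members:
        if isinstance(m, (int, np.integer)):
            if not 0 <= int(m) < len(ids):
                raise KeyError(f"index {m} not in distance matrix")
            idx.append(int(m))
        else:
            if m not in lookup:
                raise KeyError(f"id {m!r} not in distance matrix")
            idx.append(lookup[m])
    return idx


def representative(
    members: Sequence[str | int], D: DistanceMatrix | np.ndarray
) -> str:
    """Member with minimum mean squared distance to all members; ties → lowest index."""
    Dv, ids = _as_matrix(D)
    idx = _indices(members, ids)
    if not idx:
        raise ValueError("members must be non-empty")
    sub = Dv[np.ix_(idx, idx)] ** 2
    best = int(np.argmin(sub.mean(axis=1)))  # leftmost min = lowest index
    return ids[idx[best]]


def spread(
    members: Sequence[str | int],
    rep: str | int,
    D: DistanceMatrix | np.ndarray,
) -> float:
    """Cluster spread σ_D = RMS distance of the members to the representative."""
    Dv, ids = _as_matrix(D)
    idx = _indices(members, ids)
    (ridx,) = _indices([rep], ids)
    if ridx not in idx:
        raise ValueError("representative must be a member of the cluster")
    return float(np.sqrt(np.mean(Dv[idx, ridx] ** 2)))


def annotate_clusters(
    clusters: list[Cluster], D: DistanceMatrix | np.ndarray
) -> list[Cluster]:
    """Fill representative_id and spread of each cluster in place."""
    for c in clusters:
        c.representative_id = representative(c.member_ids, D)
        c.spread = spread(c.member_ids, c.representative_id, D)
    return clusters


def suggest_cut_height(tree: ClusterTree, min_child_size: int = 1) -> float:
    """Midpoint of the largest gap between consecutive sorted merge heights.

    A pragmatic default when no domain cut is specified: well-separated
    groups produce a wide gap between within-group and between-group merges.
    ``min_child_size > 1`` restricts the gap search to merges whose children
    both contain at least that many leaves, so that late merges of tiny
    outlier branches do not dominate the gap.
    """
    n = tree.n_leaves

    def size(node: int) -> int:
        return 1 if node < n else tree.merges[node - n].count

    hs = [
        m.height
        for m in tree.merges
        if min(size(m.left), size(m.right)) >= min_child_size
    ]
    if not hs:
        raise ValueError("no merges satisfy min_child_size")
    h = np.sort(hs)
    if len(h) == 1:
        return float(h[0]) / 2.0
    gaps = np.diff(h)
    k = int(np.argmax(gaps))
    return float(0.5 * (h[k] + h[k + 1]))


class RMSLinkageClustering(ClusterMixin, BaseEstimator):
    """RMS-linkage agglomerative clustering of a precomputed distance matrix.

    Attributes after ``fit``: ``tree_`` (the full merge sequence),
    ``children_``/``distances_`` (scipy-style arrays), ``labels_`` (flat
    clusters at ``distance_threshold``, or all-in-one when it is None).
    """

    def __init__(self, distance_threshold: float | None = 0.1):
        self.distance_threshold = distance_threshold

    def fit(self, X: DistanceMatrix | np.ndarray, y=None) -> "RMSLinkageClustering":
        self.tree_ = linkage(X)
        self.children_ = np.array(
            [[m.left, m.right] for m in self.tree_.merges], dtype=int
        )
        self.distances_ = self.tree_.heights
        thr = (
            self.distance_threshold
            if self.distance_threshold is not None
            else float(self.distances_.max())
        )
        clusters = cut(self.tree_, thr)
        labels = np.empty(self.tree_.n_leaves, dtype=int)
        for k, c in enumerate(clusters):
            labels[c.member_indices] = k
        self.labels_ = labels
        self.clusters_ = clusters
        return self


def linkage_table(tree: ClusterTree, path: str | Path | None = None):
    """Merge records as a DataFrame (node_a, node_b, delta, size); optional TSV."""
    import pandas as pd

    df = pd.DataFrame(
        [(m.left, m.right, m.height, m.count) for m in tree.merges],
        columns=["node_a", "node_b", "delta", "size"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def to_newick(tree: ClusterTree) -> str:
    """Newick string with branch lengths from the merge heights."""
    n = tree.n_leaves
    heights = {n + t: m.height for t, m in enumerate(tree.merges)}

    def h(node: int) -> float:
        return heights.get(node, 0.0)

    def render(node: int) -> str:
        if node < n:
            return tree.leaf_ids[node].replace(" ", "_")
        l, r = tree.children(node)
        bl = max(h(node) - h(l), 0.0)
        br = max(h(node) - h(r), 0.0)
        return f"({render(l)}:{bl:.10g},{render(r)}:{br:.10g})"

    return render(tree.root) + ";"


def plot_dendrogram(
    tree: ClusterTree,
    path: str | Path,
    cut_height: float | None = None,
    property_values: dict[str, float] | None = None,
):
    """Dendrogram figure, truncated below ``cut_height``: merged clusters are
    drawn as thick gray bars, singleton clusters as lines to the baseline.
    Purely cosmetic output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = tree.n_leaves
    order = tree.leaves_of(tree.root)
    xpos = {leaf: i for i, leaf in enumerate(order)}
    node_x: dict[int, float] = {leaf: float(x) for leaf, x in xpos.items()}
    node_h: dict[int, float] = {leaf: 0.0 for leaf in range(n)}
    thr = cut_height if cut_height is not None else 0.0
    nrows = 2 if property_values else 1
    fig, axes = plt.subplots(
        nrows,
        1,
        figsize=(8, 4 + nrows),
        sharex=True,
        gridspec_kw={"height_ratios": [4, 1]} if property_values else None,
    )
    ax = axes[0] if property_values else axes
    sub = tree.subtree_max_height()
    for t, m in enumerate(tree.merges):
        node = n + t
        xl, xr = node_x[m.left], node_x[m.right]
        node_x[node] = 0.5 * (xl + xr)
        node_h[node] = m.height
        if sub[t] <= thr:
            continue  # drawn as a bar at the cluster level below
        hl = max(node_h[m.left], thr if m.left >= n and sub[m.left - n] <= thr else node_h[m.left])
        hr = max(node_h[m.right], thr if m.right >= n and sub[m.right - n] <= thr else node_h[m.right])
        ax.plot([xl, xl, xr, xr], [hl, m.height, m.height, hr], color="k", lw=0.8)
    if cut_height is not None:
        for c in cut(tree, cut_height):
            xs = [xpos[i] for i in c.member_indices]
            if len(xs) > 1:
                ax.plot(
                    [min(xs), max(xs)], [thr, thr], color="0.6", lw=5,
                    solid_capstyle="butt",
                )
            else:
                ax.plot([xs[0], xs[0]], [0, thr], color="k", lw=1)
        ax.axhline(cut_height, color="0.8", ls=":", lw=0.8)
    ax.set_ylabel("linkage distance Δ")
    ax.set_xticks([])
    if property_values:
        vals = [property_values.get(tree.leaf_ids[i], np.nan) for i in order]
        axes[1].imshow(
            np.asarray(vals)[None, :], aspect="auto", cmap="viridis",
            extent=(-0.5, n - 0.5, 0, 1),
        )
        axes[1].set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
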