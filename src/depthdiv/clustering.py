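"""UPGMA agglomeration and the Mojena stopping rule.

Samples are clustered by size-weighted average linkage (UPGMA) on a Euclidean
distance matrix. The number of groups is chosen by the Mojena rule: over the
n-1 dendrogram fusion heights :math:`\\alpha_j`, compute the threshold
:math:`\\theta_k = \\bar\\alpha + k\\,\\hat\\sigma_\\alpha` and cut the tree
immediately before the first merge whose height strictly exceeds
:math:`\\theta_k`. The constant k defaults to 1.25.

The UPGMA and the cut are implemented here rather than delegated, because the
pipeline's contract fixes a deterministic tie-break (merge the
lexicographically smallest pair of cluster indices under original label
order) and the cut rule is the methodological core; scipy's average linkage
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

DEFAULT_MOJENA_K = 1.25


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if np.any(np.isnan(self.d)):
            raise ValueError("distance matrix contains NaN")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step; node ids follow the scipy convention
    (leaves 0..n-1, the j-th new cluster gets id n+j)."""

    left: int
    right: int
    height: float
    size: int


@dataclass
class Dendrogram:
    leaf_labels: list[str]
    merges: list[Merge] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def members(self, node: int) -> list[int]:
        """Leaf indices under ``node``, in dendrogram (left-to-right) order."""
        n = self.n_leaves
        if node < n:
            return [node]
        merge = self.merges[node - n]
        return self.members(merge.left) + self.members(merge.right)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf ordering of the full tree."""
        return self.members(self.n_leaves + len(self.merges) - 1)


@dataclass
class MojenaResult:
    k: float
    alpha_mean: float
    alpha_sd: float
    theta: float
    n_groups: int
    cut_index: int | None  # 0-based index of the first merge exceeding theta


@dataclass
class GroupAssignment:
    """sample_id -> group label G1..Gg, numbered by dendrogram leaf order."""

    groups: dict[str, str]

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))


def euclidean_distances(features: Mapping[str, Sequence[float]]) -> DistanceMatrix:
    """Pairwise Euclidean distances between per-sample feature vectors.

    Scalars are accepted and treated as 1-dimensional vectors.
    """
    labels = list(features.keys())
    vectors = []
    for label in labels:
        v = np.atleast_1d(np.asarray(features[label], dtype=float))
        vectors.append(v)
    dims = {v.shape[0] for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"feature vectors have ragged dimensions: {sorted(dims)}")
    x = np.vstack(vectors)
    return DistanceMatrix(labels=labels, d=squareform(pdist(x, metric="euclidean")))


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Size-weighted average-linkage agglomeration.

    At each step the pair of clusters with the minimal current linkage
    distance is merged (ties broken by the smallest (left, right) cluster-id
    pair); the distance from the merged cluster A∪B to any other cluster K is
    (|A| d(A,K) + |B| d(B,K)) / (|A| + |B|). Fusion heights are non-decreasing.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("clustering requires at least 2 samples")
    # active cluster id -> (row in the working matrix kept as a dict of dicts)
    dist: dict[int, dict[int, float]] = {
        i: {j: float(dm.d[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    size = {i: 1 for i in range(n)}
    dendro = Dendrogram(leaf_labels=list(dm.labels))
    next_id = n
    active = sorted(dist.keys())
    while len(active) > 1:
        best: tuple[int, int] | None = None
        best_d = math.inf
        for ai in range(len(active)):
            a = active[ai]
            for b in active[ai + 1:]:
                dab = dist[a][b]
                if dab < best_d or (dab == best_d and best is not None and (a, b) < best):
                    best_d = dab
                    best = (a, b)
        assert best is not None
        a, b = best
        merged_size = size[a] + size[b]
        dendro.merges.append(Merge(a, b, best_d, merged_size))
        new_row: dict[int, float] = {}
        for k in active:
            if k in (a, b):
                continue
            new_row[k] = (size[a] * dist[a][k] + size[b] * dist[b][k]) / merged_size
            del dist[k][a], dist[k][b]
            dist[k][next_id] = new_row[k]
        dist[next_id] = new_row
        size[next_id] = merged_size
        del dist[a], dist[b], size[a], size[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        active.sort()
        next_id += 1
    return dendro


def fusion_sd(heights: np.ndarray) -> float:
    """Spread estimator used by the Mojena threshold: the sample standard
    deviation of the fusion heights (0 when only one height exists).

    Isolated here so an alternative estimator can be swapped in one place.
    """
    if len(heights) < 2:
        return 0.0
    return float(np.std(heights, ddof=1))


def mojena_cut(
    dendro: Dendrogram, k: float = DEFAULT_MOJENA_K
) -> tuple[MojenaResult, GroupAssignment]:
    """Apply the Mojena stopping rule and label the resulting groups.

    Scanning merges in order, the first merge j* (1-based) with height
    strictly above theta_k determines n_groups = n - j* + 1, i.e. the
    partition immediately before that merge; if no height exceeds theta_k the
    tree collapses to a single group. Groups are labelled G1..Gg by the order
    of each group's first leaf in the dendrogram's left-to-right leaf order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = dendro.n_leaves
    heights = dendro.heights()
    alpha_mean = float(np.mean(heights))
    alpha_sd = fusion_sd(heights)
    theta = alpha_mean + k * alpha_sd
    cut_index: int | None = None
    for j, h in enumerate(heights):
        if h > theta:
            cut_index = j
            break
    if cut_index is None:
        n_groups = 1
        n_merges_applied = n - 1
    else:
        n_groups = n - (cut_index + 1) + 1
        n_merges_applied = cut_index
    result = MojenaResult(k=k, alpha_mean=alpha_mean, alpha_sd=alpha_sd,
                          theta=theta, n_groups=n_groups, cut_index=cut_index)

    # clusters after the first n_merges_applied merges
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    for j in range(n_merges_applied):
        m = dendro.merges[j]
        clusters[n + j] = clusters.pop(m.left) + clusters.pop(m.right)
    # order groups by their first leaf in dendrogram leaf order
    position = {leaf: pos for pos, leaf in enumerate(dendro.leaf_order())}
    ordered = sorted(clusters.values(), key=lambda mem: min(position[i] for i in mem))
    groups: dict[str, str] = {}
    for g, members in enumerate(ordered, start=1):
        for leaf in members:
            groups[dendro.leaf_labels[leaf]] = f"G{g}"
    return result, GroupAssignment(groups=groups)


def cophenetic(dendro: Dendrogram) -> DistanceMatrix:
    """Matrix of fusion heights of the lowest merge joining each leaf pair."""
    n = dendro.n_leaves
    d = np.zeros((n, n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for j, m in enumerate(dendro.merges):
        left, right = members.pop(m.left), members.pop(m.right)
        for a in left:
            for b in right:
                d[a, b] = d[b, a] = m.height
        members[n + j] = left + right
    return DistanceMatrix(labels=list(dendro.leaf_labels), d=d)


def to_newick(dendro: Dendrogram, precision: int = 6) -> str:
    """Rooted ultrametric Newick; each leaf-to-ancestor path length equals
    half the corresponding fusion height."""
    n = dendro.n_leaves
    # node height above the leaves (half fusion height); leaves sit at 0
    node_height = {i: 0.0 for i in range(n)}

    def fmt(x: float) -> str:
        return f"{round(x, precision):g}"

    def render(node: int) -> str:
        if node < n:
            return dendro.leaf_labels[node]
        m = dendro.merges[node - n]
        h = m.height / 2.0
        parts = []
        for child in (m.left, m.right):
            rendered = render(child)  # populates node_height[child] for internal nodes
            bl = h - node_height[child]
            parts.append(f"{rendered}:{fmt(bl)}")
        node_height[node] = h
        return "(" + ",".join(parts) + ")"

    root = n + len(dendro.merges) - 1
    return render(root) + ";"


class MojenaUPGMA:
    """scikit-learn-style clusterer: UPGMA + Mojena cut on feature rows.

    Parameters
    ----------
    k : float
        Mojena constant; the threshold is mean + k * sd of fusion heights.

    Attributes (after fit)
    ----------------------
    labels_ : ndarray of int
        Zero-based group index per sample (G1 -> 0, ...).
    n_clusters_ : int
    dendrogram_ : Dendrogram
    mojena_ : MojenaResult
    """

    def __init__(self, k: float = DEFAULT_MOJENA_K):
        self.k = k

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k}

    def set_params(self, **params) -> "MojenaUPGMA":
        for key, value in params.items():
            if key != "k":
                raise ValueError(f"unknown parameter {key!r}")
            self.k = value
        return self

    def fit(self, X, y=None) -> "MojenaUPGMA":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        labels = [str(i) for i in range(X.shape[0])]
        dm = euclidean_distances({lab: row for lab, row in zip(labels, X)})
        self.dendrogram_ = upgma(dm)
        self.mojena_, assignment = mojena_cut(self.dendrogram_, k=self.k)
        self.n_clusters_ = assignment.n_groups
        self.labels_ = np.array(
            [int(assignment.groups[lab][1:]) - 1 for lab in labels]
        )
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
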