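import math

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import clone

from depthdiv.clustering import (
    Dendrogram,
    DistanceMatrix,
    Merge,
    MojenaUPGMA,
    cophenetic,
    euclidean_distances,
    mojena_cut,
    to_newick,
    upgma,
)


def naive_upgma_heights(d):
    """Independent oracle: average linkage recomputed from the *leaf-pair*
    distances at every step (quadratic scan, no running linkage updates)."""
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best, best_d = None, math.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pairs = [(a, b) for a in clusters[i] for b in clusters[j]]
                avg = sum(d[a, b] for a, b in pairs) / len(pairs)
                if avg < best_d:
                    best_d, best = avg, (i, j)
        i, j = best
        heights.append(best_d)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return np.array(heights)


def random_distance_matrix(rng, n):
    x = rng.uniform(0, 10, size=(n, 1 + rng.integers(0, 3)))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"s{i}" for i in range(n)], d)


class TestEuclideanDistances:
    def test_scalar_difference(self):
        dm = euclidean_distances({"a": [0.4], "b": [0.6]})
        assert dm.d[0, 1] == pytest.approx(0.2)

    def test_identical_vectors(self):
        dm = euclidean_distances({"a": [1, 2], "b": [1, 2]})
        assert dm.d[0, 1] == 0.0

    def test_three_four_five(self):
        dm = euclidean_distances({"a": (0, 0), "b": (3, 4)})
        assert dm.d[0, 1] == pytest.approx(5.0)

    def test_ragged_dimensions(self):
        with pytest.raises(ValueError, match="ragged"):
            euclidean_distances({"a": [1], "b": [1, 2]})


class TestUPGMA:
    def test_hand_example(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 8], [2, 0, 6], [8, 6, 0]], float))
        dendro = upgma(dm)
        assert [(m.left, m.right, m.height) for m in dendro.merges] == [
            (0, 1, 2.0), (2, 3, 7.0),
        ]

    def test_all_equal_distances(self):
        d = np.full((3, 3), 4.0)
        np.fill_diagonal(d, 0.0)
        dendro = upgma(DistanceMatrix(["a", "b", "c"], d))
        assert dendro.heights().tolist() == [4.0, 4.0]

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["a"], np.zeros((1, 1))))

    def test_nan_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="NaN"):
            DistanceMatrix(["a", "b"], d)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            dm = random_distance_matrix(rng, int(rng.integers(3, 13)))
            ours = upgma(dm).heights()
            assert np.allclose(ours, naive_upgma_heights(dm.d), atol=1e-9)

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            dm = random_distance_matrix(rng, int(rng.integers(3, 13)))
            ours = upgma(dm).heights()
            scipy_heights = linkage(squareform(dm.d, checks=False), method="average")[:, 2]
            assert np.allclose(ours, scipy_heights, atol=1e-9)

    def test_monotone_heights(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            # arbitrary (possibly non-metric) symmetric dissimilarities
            d = rng.uniform(0.1, 5, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            heights = upgma(DistanceMatrix([str(i) for i in range(n)], d)).heights()
            assert np.all(np.diff(heights) >= -1e-12)

    def test_size_accounting(self):
        rng = np.random.default_rng(5)
        dm = random_distance_matrix(rng, 9)
        dendro = upgma(dm)
        assert dendro.merges[-1].size == 9
        assert sorted(dendro.leaf_order()) == list(range(9))


class TestMojenaCut:
    def test_worked_example(self):
        heights = [1.0, 1.1, 1.2, 5.0]
        dendro = Dendrogram(
            leaf_labels=list("abcde"),
            merges=[Merge(0, 1, heights[0], 2), Merge(2, 3, heights[1], 2),
                    Merge(5, 6, heights[2], 4), Merge(4, 7, heights[3], 5)],
        )
        result, assignment = mojena_cut(dendro, k=1.25)
        assert result.alpha_mean == pytest.approx(2.075)
        assert result.alpha_sd == pytest.approx(1.9517, abs=1e-4)
        assert result.theta == pytest.approx(4.5146, abs=1e-4)
        assert result.n_groups == 2
        assert assignment.n_groups == 2
        sizes = sorted(
            list(assignment.groups.values()).count(g)
            for g in set(assignment.groups.values())
        )
        assert sizes == [1, 4]

    def test_all_heights_equal_one_group(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        result, assignment = mojena_cut(upgma(DistanceMatrix(list("abcd"), d)))
        assert result.n_groups == 1
        assert set(assignment.groups.values()) == {"G1"}

    def test_two_leaves_single_height(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 3.0], [3.0, 0]]))
        result, _ = mojena_cut(upgma(dm))
        # sd of a single height is defined as 0, theta equals the height,
        # and the strict inequality leaves a single group
        assert result.alpha_sd == 0.0
        assert result.n_groups == 1

    def test_group_labels_follow_leaf_order(self):
        x = {"a": [0.0], "b": [0.1], "c": [10.0], "d": [10.1]}
        dendro = upgma(euclidean_distances(x))
        _, assignment = mojena_cut(dendro)
        first_leaf = dendro.leaf_labels[dendro.leaf_order()[0]]
        assert assignment.groups[first_leaf] == "G1"

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(17)
        points = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(5, 0.1, 6),
                                 rng.normal(12, 0.1, 6)])
        labels = [f"s{i}" for i in range(18)]
        _, base = mojena_cut(upgma(euclidean_distances(
            dict(zip(labels, points[:, None])))))
        perm = rng.permutation(18)
        _, permuted = mojena_cut(upgma(euclidean_distances(
            {labels[i]: [points[i]] for i in perm})))
        assert base.n_groups == permuted.n_groups
        def size_multiset(a):
            values = list(a.groups.values())
            return sorted(values.count(g) for g in set(values))
        assert size_multiset(base) == size_multiset(permuted)
        # same partition of the same samples, up to relabelling
        def partition(a):
            groups = {}
            for s, g in a.groups.items():
                groups.setdefault(g, set()).add(s)
            return {frozenset(v) for v in groups.values()}
        assert partition(base) == partition(permuted)

    @pytest.mark.parametrize("g", [2, 3, 4])
    def test_planted_cluster_recovery(self, g):
        rng = np.random.default_rng(100 + g)
        hits = 0
        for _ in range(20):
            centers = np.arange(g) * 10.0
            points = np.concatenate(
                [c + rng.uniform(-0.25, 0.25, size=8) for c in centers]
            )
            features = {f"s{i}": [v] for i, v in enumerate(points)}
            result, _ = mojena_cut(upgma(euclidean_distances(features)))
            hits += result.n_groups == g
        assert hits >= 19


class TestCophenetic:
    def test_hand_example(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 8], [2, 0, 6], [8, 6, 0]], float))
        coph = cophenetic(upgma(dm))
        assert coph.d[0, 1] == 2.0
        assert coph.d[0, 2] == coph.d[1, 2] == 7.0
        assert np.all(np.diag(coph.d) == 0)

    def test_ultrametric_inequality(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            dm = random_distance_matrix(rng, int(rng.integers(3, 10)))
            c = cophenetic(upgma(dm)).d
            n = c.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert c[i, j] <= max(c[i, k], c[j, k]) + 1e-12


class TestNewick:
    def test_two_leaf_half_height(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 2.0], [2.0, 0]]))
        assert to_newick(upgma(dm)) == "(A:1,B:1);"

    def test_three_leaf_branch_lengths(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 8], [2, 0, 6], [8, 6, 0]], float))
        tree = dendropy.Tree.get(data=to_newick(upgma(dm)), schema="newick")
        depths = {}
        tree.calc_node_root_distances()
        for leaf in tree.leaf_node_iter():
            depths[leaf.taxon.label] = leaf.root_distance
        # ultrametric: every leaf sits at half the root fusion height
        assert all(v == pytest.approx(3.5) for v in depths.values())
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(2.0)
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(7.0)

    def test_round_trip_topology(self):
        rng = np.random.default_rng(23)
        dm = random_distance_matrix(rng, 8)
        dendro = upgma(dm)
        tree = dendropy.Tree.get(data=to_newick(dendro), schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == sorted(dm.labels)
        # cophenetic distances survive the round trip
        coph = cophenetic(dendro)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        coph.d[i, j], abs=1e-5
                    )


class TestMojenaUPGMAEstimator:
    def test_sklearn_protocol(self):
        est = MojenaUPGMA(k=2.0)
        assert clone(est).get_params() == {"k": 2.0}
        est.set_params(k=1.25)
        assert est.k == 1.25

    def test_fit_predict_matches_functions(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.05, 8), rng.normal(4, 0.05, 8)])
        labels = MojenaUPGMA().fit_predict(x)
        assert len(set(labels)) == 2
        # points from the same blob share a label
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
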