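"""Distances, dendrograms, cuts, centroids, partition agreement."""

import numpy as np
import pandas as pd
import pytest

from dietmeta import cluster, simulate


class TestDistances:
    def test_squared_euclidean_hand_values(self):
        assert cluster.squared_euclidean([1, 2], [4, 6]) == 25.0
        assert cluster.squared_euclidean([3, 3], [3, 3]) == 0.0
        assert cluster.squared_euclidean([0, 1, 0], [0, 0, 0]) == 1.0

    def test_squared_euclidean_length_mismatch(self):
        with pytest.raises(cluster.ClusterError, match="length"):
            cluster.squared_euclidean([1, 2], [1, 2, 3])

    def test_bray_curtis_hand_values(self):
        assert cluster.bray_curtis([2, 2], [2, 0]) == pytest.approx(1 / 3)
        assert cluster.bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert cluster.bray_curtis([1, 0], [0, 5]) == 1.0  # disjoint support

    def test_bray_curtis_rejects_degenerate_input(self):
        with pytest.raises(cluster.ClusterError, match="all-zero"):
            cluster.bray_curtis([0, 0], [0, 0])
        with pytest.raises(cluster.ClusterError, match="non-negative"):
            cluster.bray_curtis([-1, 2], [1, 2])

    def test_bray_curtis_bounded(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 10, 6)
            y = rng.uniform(0, 10, 6)
            d = cluster.bray_curtis(x, y)
            assert 0.0 <= d <= 1.0

    def test_variable_distance_matrix_properties(self, rng):
        data = pd.DataFrame(rng.uniform(0, 5, (20, 6)),
                            columns=list("abcdef"))
        for metric in ("sqeuclidean", "braycurtis"):
            dm = cluster.variable_distances(data, metric)
            arr = dm.values.to_numpy()
            assert np.allclose(arr, arr.T)
            assert np.allclose(np.diag(arr), 0.0)
            assert (arr >= 0).all()
            assert dm.values.loc["a", "b"] == pytest.approx(
                getattr(cluster, "squared_euclidean"
                        if metric == "sqeuclidean" else "bray_curtis")(
                    data["a"], data["b"]))


def _brute_heights(dist: np.ndarray, linkage: str) -> list[float]:
    """Brute-force agglomeration oracle over explicit member sets."""
    active = {i: (i,) for i in range(len(dist))}

    def cluster_distance(a, b):
        pair_d = [dist[i, j] for i in active[a] for j in active[b]]
        return max(pair_d) if linkage == "complete" else float(np.mean(pair_d))

    heights = []
    next_id = len(dist)
    while len(active) > 1:
        ids = sorted(active)
        best = min(((a, b) for i, a in enumerate(ids) for b in ids[i + 1:]),
                   key=lambda ab: (cluster_distance(*ab), ab))
        heights.append(cluster_distance(*best))
        active[next_id] = active.pop(best[0]) + active.pop(best[1])
        next_id += 1
    return heights


@pytest.mark.parametrize("linkage", ["complete", "average"])
@pytest.mark.parametrize("n", [5, 8])
def test_merge_heights_match_brute_force_oracle(rng, linkage, n):
    points = rng.normal(0, 1, (n, 4))
    dist = np.array([[cluster.squared_euclidean(points[i], points[j])
                      for j in range(n)] for i in range(n)])
    dm = cluster.DistanceMatrix(
        values=pd.DataFrame(dist, index=list(range(n)),
                            columns=list(range(n))),
        metric="sqeuclidean")
    model = cluster.hierarchical_cluster(dm, linkage=linkage)
    expected = _brute_heights(dist, linkage)
    assert np.allclose(sorted(model.merge_heights), sorted(expected),
                       atol=1e-10)


class TestDendrogram:
    @pytest.fixture()
    def three_point_model(self):
        d = pd.DataFrame([[0, 1, 10], [1, 0, 10], [10, 10, 0]],
                         index=list("xyz"), columns=list("xyz"), dtype=float)
        return cluster.hierarchical_cluster(
            cluster.DistanceMatrix(d, "sqeuclidean"))

    def test_nearest_pair_merges_first(self, three_point_model):
        assert three_point_model.merge_heights[0] == 1.0
        two = cluster.cut_dendrogram(three_point_model, 5.0)
        assert two["x"] == two["y"] != two["z"]

    def test_heights_monotone_non_decreasing(self, tiny_run):
        for model in tiny_run.cluster_models.values():
            assert (np.diff(model.merge_heights) >= -1e-12).all()

    def test_permutation_invariance(self, rng):
        data = pd.DataFrame(rng.uniform(0, 3, (15, 6)),
                            columns=list("abcdef"))
        base = cluster.cut_dendrogram(cluster.hierarchical_cluster(
            cluster.variable_distances(data, "sqeuclidean")), 5.0)
        shuffled_cols = list("fcadbe")
        perm = cluster.cut_dendrogram(cluster.hierarchical_cluster(
            cluster.variable_distances(data[shuffled_cols], "sqeuclidean")),
            5.0)
        assert cluster.clustering_agreement(base, perm) == pytest.approx(1.0)

    def test_cut_above_root_gives_one_cluster(self, three_point_model):
        cut = cluster.cut_dendrogram(three_point_model, 1e9)
        assert cut.nunique() == 1

    def test_cut_at_zero_gives_singletons(self, three_point_model):
        cut = cluster.cut_dendrogram(three_point_model, 0.0)
        assert cut.nunique() == 3

    def test_cluster_count_non_increasing_in_height(self, rng):
        data = pd.DataFrame(rng.uniform(0, 3, (20, 8)))
        model = cluster.hierarchical_cluster(
            cluster.variable_distances(data, "sqeuclidean"))
        counts = [cluster.cut_dendrogram(model, h).nunique()
                  for h in np.linspace(0, model.merge_heights[-1] + 1, 12)]
        assert (np.diff(counts) <= 0).all()

    def test_five_point_fixture_cut_between_merges(self, rng):
        points = rng.normal(0, 1, (5, 3))
        data = pd.DataFrame(points.T)  # 3 subjects x 5 variables
        model = cluster.hierarchical_cluster(
            cluster.variable_distances(data, "sqeuclidean"))
        h1, h2 = model.merge_heights[0], model.merge_heights[1]
        cut = cluster.cut_dendrogram(model, (h1 + h2) / 2.0)
        assert cut.nunique() == 4

    def test_newick_export_parses_and_preserves_heights(self, three_point_model):
        import io

        from Bio import Phylo

        newick = cluster.to_newick(three_point_model)
        tree = Phylo.read(io.StringIO(newick), "newick")
        leaves = {leaf.name for leaf in tree.get_terminals()}
        assert leaves == {"x", "y", "z"}
        # root-to-leaf path length equals the root merge height
        root_height = three_point_model.merge_heights[-1]
        for leaf in tree.get_terminals():
            assert tree.distance(leaf) == pytest.approx(root_height, rel=1e-9)


class TestCentroids:
    def test_singleton_cluster_equals_variable(self, rng):
        data = pd.DataFrame(rng.uniform(0, 1, (6, 3)), columns=list("abc"))
        memberships = pd.Series([1, 2, 3], index=list("abc"))
        centroids = cluster.compute_centroids(data, memberships)
        assert np.allclose(centroids["cluster_1"], data["a"])

    def test_mean_of_members(self):
        data = pd.DataFrame({"a": [1.0], "b": [3.0]})
        centroids = cluster.compute_centroids(
            data, pd.Series([1, 1], index=["a", "b"]))
        assert centroids.loc[0, "cluster_1"] == 2.0

    def test_masked_values_excluded_and_all_missing_propagates(self):
        data = pd.DataFrame({"a": [1.0, np.nan], "b": [3.0, np.nan]})
        centroids = cluster.compute_centroids(
            data, pd.Series([1, 1], index=["a", "b"]))
        assert centroids.iloc[0, 0] == 2.0
        assert np.isnan(centroids.iloc[1, 0])

    def test_unknown_variable_is_an_error(self):
        data = pd.DataFrame({"a": [1.0]})
        with pytest.raises(cluster.ClusterError, match="unknown"):
            cluster.compute_centroids(data, pd.Series([1], index=["zz"]))


class TestAgreement:
    def test_identical_partitions(self):
        a = pd.Series([1, 1, 2, 2], index=list("wxyz"))
        b = pd.Series([5, 5, 9, 9], index=list("wxyz"))
        assert cluster.clustering_agreement(a, b) == 1.0

    def test_crossed_pairs_fixture(self):
        # {AB|CD} vs {AC|BD}: contingency 2x2 of ones -> ARI = -0.5
        a = pd.Series([1, 1, 2, 2], index=list("ABCD"))
        b = pd.Series([1, 2, 1, 2], index=list("ABCD"))
        assert cluster.clustering_agreement(a, b) == pytest.approx(-0.5)

    def test_degenerate_partitions_score_zero(self):
        a = pd.Series([1, 2, 3, 4], index=list("ABCD"))
        b = pd.Series([1, 1, 1, 1], index=list("ABCD"))
        assert cluster.clustering_agreement(a, b) == pytest.approx(0.0)

    def test_variable_set_mismatch_rejected(self):
        a = pd.Series([1, 2], index=["u", "v"])
        b = pd.Series([1, 2], index=["u", "w"])
        with pytest.raises(cluster.ClusterError, match="different variable"):
            cluster.clustering_agreement(a, b)

    def test_ari_matches_contingency_formula_oracle(self, rng):
        from math import comb

        labels_a = rng.integers(0, 3, 30)
        labels_b = rng.integers(0, 4, 30)
        idx = [f"v{i}" for i in range(30)]
        got = cluster.clustering_agreement(pd.Series(labels_a, index=idx),
                                           pd.Series(labels_b, index=idx))
        table = pd.crosstab(labels_a, labels_b).to_numpy()
        index = sum(comb(int(n), 2) for n in table.ravel())
        row = sum(comb(int(n), 2) for n in table.sum(1))
        col = sum(comb(int(n), 2) for n in table.sum(0))
        total = comb(30, 2)
        expected_index = row * col / total
        max_index = (row + col) / 2
        assert got == pytest.approx(
            (index - expected_index) / (max_index - expected_index), abs=1e-12)


def test_planted_food_blocks_recoverable_at_some_cut():
    config = simulate.null_config(
        n_per_cohort=(150, 80, 80, 60), n_foods=16, n_food_blocks=4,
        block_corr=0.7, n_taxa=5, n_pathways=5, seed=9)
    ds = simulate.simulate_cohorts(config)
    model = cluster.hierarchical_cluster(
        cluster.variable_distances(ds.intake, "sqeuclidean",
                                   standardize=True))
    ari, _ = cluster.best_cut_agreement(model, ds.food_blocks)
    assert ari >= 0.9
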